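"""Region selection, MLP LOOCV scoring and ROC/AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

import corticospec as cs
from corticospec.classify import MlpSpec, mlp_loocv_scores, regionwise_glm, roc_auc


def _dataset(atlas, values, cohort):
    thickness = pd.DataFrame(
        values, index=list(cohort["subject_id"]), columns=list(atlas["region_name"])
    )
    return cs.ThicknessDataset(thickness=thickness, cohort=cohort, atlas=atlas)


class TestAuc:
    def test_perfect_and_inverted_separation(self):
        roc = roc_auc(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert roc.auc == 1.0
        assert roc_auc(np.array([1.0, 2, 3, 4]), np.array([1, 1, 0, 0])).auc == 0.0

    def test_six_point_brute_force_value(self):
        """Enumerating the nine positive-negative pairs gives 6 wins -> 2/3."""
        scores = np.array([1.0, 2, 3, 4, 5, 6])
        labels = np.array([0, 1, 0, 1, 0, 1])
        wins = sum(
            float(s_pos > s_neg) + 0.5 * float(s_pos == s_neg)
            for s_pos in scores[labels == 1]
            for s_neg in scores[labels == 0]
        )
        assert wins / 9 == pytest.approx(2 / 3)
        assert roc_auc(scores, labels).auc == pytest.approx(2 / 3)

    def test_matches_sklearn_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            scores = rng.integers(0, 5, size=30).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                roc_auc_score(labels, scores)
            )

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(1)
        roc = roc_auc(rng.normal(size=40), rng.integers(0, 2, size=40))
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    @settings(max_examples=40, deadline=None)
    @given(
        seed=st.integers(0, 1000),
        scale=st.floats(0.1, 10),
        shift=st.floats(-5, 5),
    )
    def test_invariant_under_strictly_monotone_transforms(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = np.array([0, 1] * 10)
        base = roc_auc(scores, labels).auc
        assert roc_auc(scale * scores + shift, labels).auc == pytest.approx(base)
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base)

    def test_complement_identity_for_tie_free_scores(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = rng.permutation([0] * 15 + [1] * 15)
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc == pytest.approx(1.0)


class TestRegionwiseGlm:
    def test_null_selection_rate_is_one_tail_of_five_percent(self, atlas, two_group_cohort):
        rng = np.random.default_rng(3)
        rates = []
        for _ in range(150):
            cohort = two_group_cohort(rng, 10, 10)
            ds = _dataset(atlas, 2.7 + 0.2 * rng.standard_normal((20, 68)), cohort)
            glm = regionwise_glm(ds, ("HC", "LTLE"))
            rates.append(glm["selected"].mean())
        # negative coefficient AND p < .05 two-sided -> one 2.5% tail
        assert np.mean(rates) == pytest.approx(0.025, abs=0.006)

    def test_injected_effect_is_detected(self, atlas, two_group_cohort):
        rng = np.random.default_rng(4)
        hits = 0
        reps = 50
        for _ in range(reps):
            cohort = two_group_cohort(rng, 20, 19)
            values = 2.7 + 0.15 * rng.standard_normal((39, 68))
            values[(cohort["group"] == "LTLE").to_numpy(), 5] -= 0.5
            ds = _dataset(atlas, values, cohort)
            glm = regionwise_glm(ds, ("HC", "LTLE"))
            hits += bool(glm.loc[5, "selected"])
        assert hits >= int(0.95 * reps)

    def test_zero_variance_region_raises(self, atlas, two_group_cohort):
        rng = np.random.default_rng(5)
        cohort = two_group_cohort(rng, 5, 5)
        values = 2.7 + 0.1 * rng.standard_normal((10, 68))
        values[:, 7] = 2.5
        ds = _dataset(atlas, values, cohort)
        with pytest.raises(ValueError, match="zero variance"):
            regionwise_glm(ds, ("HC", "LTLE"))

    def test_missing_group_raises(self, atlas, two_group_cohort):
        rng = np.random.default_rng(6)
        cohort = two_group_cohort(rng, 5, 5)
        ds = _dataset(atlas, 2.7 + 0.1 * rng.standard_normal((10, 68)), cohort)
        with pytest.raises(ValueError):
            regionwise_glm(ds, ("HC", "RTLE"))


class TestMlp:
    def test_separated_classes_order_correctly(self):
        rng = np.random.default_rng(7)
        feats = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)])[:, None]
        labels = np.repeat([0, 1], 10)
        scores = mlp_loocv_scores(feats, labels, MlpSpec(seed=0))
        assert roc_auc(scores, labels).auc == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        feats = rng.normal(size=(16, 3))
        labels = np.repeat([0, 1], 8)
        spec = MlpSpec(hidden_units=3, seed=5)
        np.testing.assert_array_equal(
            mlp_loocv_scores(feats, labels, spec),
            mlp_loocv_scores(feats, labels, spec),
        )

    def test_label_permutation_null_auc_near_half(self):
        from corticospec.validation import classifier_checks

        out = classifier_checks(seed=0, n_permutations=12)
        assert abs(out["permutation_null_mean_auc"] - 0.5) <= 0.12

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            mlp_loocv_scores(np.ones((4, 1)), np.array([0, 0, 0, 1]), MlpSpec())
        with pytest.raises(ValueError):
            mlp_loocv_scores(np.ones((4, 0)), np.array([0, 0, 1, 1]), MlpSpec())
        with pytest.raises(ValueError):
            MlpSpec(hidden_units=0)


def test_model_selected_regions_beat_random_region_sets(atlas, basis7, two_group_cohort):
    """Features from the model's thinning map should classify at least as
    well as random region sets of the same size, most of the time."""
    rng = np.random.default_rng(9)
    cohort = two_group_cohort(rng, 15, 15)
    truth = cs.default_truth(atlas, J=9, L=7, seed=90, group_effect=-0.35)
    ds = cs.simulate_thickness(atlas, cohort, truth, basis7)
    samples = cs.fit_thickness_model(
        ds, cs.ModelConfig(iterations=1200, burn_in=400, thinning=4, seed=91)
    )
    summary = cs.posterior_zscores(samples)
    z = summary.zscore.loc["LTLE"]
    selected = list(z.nsmallest(6).index)
    labels = (ds.cohort["group"] == "LTLE").to_numpy(dtype=int)
    spec = MlpSpec(hidden_units=3, max_epochs=300, seed=1)
    auc_bayes = roc_auc(
        mlp_loocv_scores(ds.thickness[selected].to_numpy(), labels, spec), labels
    ).auc
    wins = 0
    trials = 12
    for _ in range(trials):
        random_set = list(rng.choice(ds.thickness.columns, size=6, replace=False))
        auc_rand = roc_auc(
            mlp_loocv_scores(ds.thickness[random_set].to_numpy(), labels, spec), labels
        ).auc
        wins += auc_bayes >= auc_rand
    assert wins >= int(0.8 * trials)
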