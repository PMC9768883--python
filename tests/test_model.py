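"""Spectral transform, MCMC engine and posterior summaries."""

import dataclasses

import numpy as np
import pytest

import corticospec as cs
from corticospec.model import (
    McmcSamples,
    posterior_zscores,
    run_mcmc,
    spatial_coefficient_draws,
    transform_dataset,
)

from conftest import random_sphere_points


class TestTransform:
    def test_study_scale_shape(self, small_ds, basis7):
        sp = transform_dataset(small_ds, basis7)
        assert sp.matrix.shape == (53, 64)
        assert sp.subject_ids == tuple(small_ds.thickness.index)

    def test_linearity_through_dataset_mixtures(self, atlas, table1, basis7, truth):
        ds1 = cs.simulate_thickness(atlas, table1, truth, basis7)
        truth2 = dataclasses.replace(truth, seed=truth.seed + 1)
        ds2 = cs.simulate_thickness(atlas, table1, truth2, basis7)
        mid = cs.ThicknessDataset(
            thickness=(ds1.thickness + ds2.thickness) / 2,
            cohort=table1,
            atlas=atlas,
        )
        lhs = transform_dataset(mid, basis7).matrix
        rhs = (
            transform_dataset(ds1, basis7).matrix
            + transform_dataset(ds2, basis7).matrix
        ) / 2
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_misaligned_basis_raises(self, small_ds):
        rng = np.random.default_rng(0)
        other = cs.build_basis(random_sphere_points(rng, 68), 7)
        with pytest.raises(ValueError, match="misaligned|points"):
            transform_dataset(small_ds, other)


class TestMcmcMechanics:
    def test_retained_draw_count_and_determinism(self, basis7):
        rng = np.random.default_rng(1)
        m = 12
        X = np.column_stack([np.ones(m), rng.normal(size=(m, 1))])
        y = rng.normal(size=(m, 64))
        config = cs.ModelConfig(iterations=300, burn_in=100, thinning=4, seed=9, J=4)
        s1 = run_mcmc(y, X, basis7, config)
        s2 = run_mcmc(y, X, basis7, config)
        assert s1.n_retained == (300 - 100) // 4
        np.testing.assert_array_equal(s1.b_tilde, s2.b_tilde)
        np.testing.assert_array_equal(s1.sigma, s2.sigma)
        s3 = run_mcmc(y, X, basis7, dataclasses.replace(config, seed=10))
        assert not np.array_equal(s1.b_tilde, s3.b_tilde)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            cs.ModelConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            cs.ModelConfig(thinning=0)
        with pytest.raises(ValueError):
            cs.ModelConfig(J=65, L=7)
        with pytest.raises(ValueError):
            cs.ModelConfig(residual="banana")

    def test_nonfinite_data_rejected(self, basis7):
        X = np.ones((5, 1))
        y = np.zeros((5, 64))
        y[0, 0] = np.inf
        with pytest.raises(ValueError):
            run_mcmc(y, X, basis7, cs.ModelConfig(iterations=10, burn_in=5, J=4))

    def test_intercept_column_required(self, basis7):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="intercept"):
            run_mcmc(np.zeros((5, 64)), X, basis7, cs.ModelConfig(iterations=10, burn_in=5))


def test_gibbs_matches_conjugate_closed_form():
    """With frozen variance blocks the tractable configuration is pure
    conjugate Gibbs; retained draws are iid from the exact normal posterior."""
    from corticospec.validation import gibbs_closed_form_gap

    gap = gibbs_closed_form_gap(seed=0)
    assert gap["max_abs_z"] < 3.0


def test_horseshoe_shrinks_null_coefficients_at_least_as_much_as_gaussian():
    """On null data the half-Cauchy local scales should shrink the
    nonstationary prior-mean coefficients harder than the Gaussian prior,
    on average over replicates."""
    rng = np.random.default_rng(5)
    pts = random_sphere_points(np.random.default_rng(11), 40)
    basis = cs.build_basis(pts, 3)
    m, reps = 16, 12
    gaps = []
    for rep in range(reps):
        X = np.column_stack([np.ones(m), rng.normal(size=(m, 2))])
        y = 0.1 * rng.normal(size=(m, basis.n_columns))
        means = {}
        for prior in ("gaussian", "horseshoe"):
            config = cs.ModelConfig(
                residual="independent", fe_prior=prior, nonstationary=True,
                J=4, L=3, iterations=700, burn_in=200, thinning=2, seed=100 + rep,
            )
            s = run_mcmc(y, X, basis, config)
            means[prior] = np.mean(np.abs(s.beta[:, 1:, :].mean(axis=0)))
        gaps.append(means["gaussian"] - means["horseshoe"])
    assert np.mean(gaps) >= 0.0


def test_group_effect_recovery_on_strong_signal(atlas, basis7, two_group_cohort):
    """A strong injected thinning effect is recovered: the posterior mean
    tracks the true surface and its sign at the deepest regions."""
    rng = np.random.default_rng(21)
    cohort = two_group_cohort(rng, 20, 20)
    truth = cs.default_truth(atlas, J=9, L=7, seed=77, group_effect=-0.3)
    ds = cs.simulate_thickness(atlas, cohort, truth, basis7)
    config = cs.ModelConfig(iterations=1500, burn_in=500, thinning=5, seed=3)
    samples = cs.fit_thickness_model(ds, config)
    draws = spatial_coefficient_draws(samples)
    k = list(samples.covariate_names).index("LTLE")
    est = draws[:, k, :].mean(axis=0)
    true_effect = truth.coefficients[3]
    assert np.corrcoef(est, true_effect)[0, 1] > 0.3
    deepest = np.argsort(true_effect)[:5]
    assert np.all(est[deepest] < 0)


class TestPosteriorSummary:
    @staticmethod
    def _samples_from_btilde(b_tilde, basis):
        S, q, nw = b_tilde.shape
        return McmcSamples(
            b_tilde=b_tilde,
            beta=np.zeros((S, q, 4)),
            gamma=np.zeros((S, 1, 4)),
            sigma=np.tile(np.eye(4), (S, 1, 1)),
            nu3=np.ones(S),
            theta_residual=np.ones((S, 4)),
            theta_intercept=np.ones((S, 4)),
            theta_slopes=np.ones((S, 4)),
            acceptance={},
            config=cs.ModelConfig(iterations=10, burn_in=1, J=4),
            basis=basis,
            covariate_names=tuple(f"x{k}" for k in range(q)),
            region_names=tuple(f"r{i}" for i in range(basis.n_points)),
        )

    def test_constant_draws_error_names_the_region(self, basis7):
        b = np.tile(np.zeros((1, 2, 64)), (5, 1, 1))
        b[:, :, 0] = 2.0  # constant across draws -> sd 0 everywhere
        samples = self._samples_from_btilde(b, basis7)
        with pytest.raises(ValueError, match="degenerate chain.*x0"):
            posterior_zscores(samples)

    def test_constructed_mean_and_sd_give_z_two(self, basis7):
        rng = np.random.default_rng(0)
        S = 4000
        spatial = 2.0 + rng.standard_normal((S, 1, 68))
        # invert to spectral draws so posterior_zscores round-trips them;
        # the span projection rescales each region's sd to sqrt(P_vv)
        pinv = np.linalg.pinv(basis7.matrix)
        proj_diag = np.einsum("vw,wv->v", basis7.matrix, pinv)
        b = spatial @ pinv.T
        samples = self._samples_from_btilde(b, basis7)
        summary = posterior_zscores(samples)
        expected = 2.0 / np.sqrt(proj_diag)
        assert np.allclose(summary.zscore.to_numpy()[0], expected, atol=0.15)

    def test_negating_draws_negates_z(self, fitted_samples):
        base = posterior_zscores(fitted_samples)
        flipped = dataclasses.replace(
            fitted_samples, b_tilde=-fitted_samples.b_tilde
        )
        neg = posterior_zscores(flipped)
        np.testing.assert_allclose(
            neg.zscore.to_numpy(), -base.zscore.to_numpy(), atol=1e-10
        )

    def test_needs_at_least_two_draws(self, basis7):
        samples = self._samples_from_btilde(np.zeros((1, 2, 64)), basis7)
        with pytest.raises(ValueError):
            posterior_zscores(samples)
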