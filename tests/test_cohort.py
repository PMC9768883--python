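"""Synthetic atlas, demographics fixture and thickness generator."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

import corticospec as cs


class TestAtlas:
    def test_deterministic_given_seed(self):
        pd.testing.assert_frame_equal(cs.make_atlas(3), cs.make_atlas(3))
        assert not cs.make_atlas(3).equals(cs.make_atlas(4))

    def test_hemisphere_split_and_names(self, atlas):
        assert len(atlas) == 68
        assert (atlas["region_name"].str.endswith("_lh").sum()) == 34
        assert (atlas["region_name"].str.endswith("_rh").sum()) == 34
        assert atlas["region_name"].is_unique
        left = atlas.loc[atlas["hemisphere"] == "L", "longitude_rad"]
        right = atlas.loc[atlas["hemisphere"] == "R", "longitude_rad"]
        assert (left < np.pi).all() and (right >= np.pi).all()

    def test_minimum_pairwise_separation(self, points):
        vecs = np.array([p.unit_vector() for p in points])
        assert pdist(vecs).min() > 0.05


class TestTable1Fixture:
    def test_group_sizes_and_sex_counts(self, table1):
        counts = table1.groupby("group").size()
        assert counts.to_dict() == {"HC": 20, "LTLE": 19, "RTLE": 14}
        males = table1[table1.sex == "M"].groupby("group").size()
        assert males.to_dict() == {"HC": 10, "LTLE": 11, "RTLE": 10}

    def test_reproduces_published_sex_chisq(self, table1):
        from corticospec.demographics import sex_contingency

        stat, df, _ = cs.chisq_homogeneity(sex_contingency(table1))
        assert round(stat, 2) == 1.56
        assert df == 2

    def test_reproduces_published_age_anova(self, table1):
        from corticospec.demographics import age_summaries

        F, df1, df2, _ = cs.anova_from_summary(age_summaries(table1))
        assert round(F, 2) == 1.92
        assert (df1, df2) == (2, 50)

    def test_group_age_moments_match_published_values(self, table1):
        published = {"HC": (27.95, 6.32), "LTLE": (32.10, 8.47), "RTLE": (28.28, 6.28)}
        for group, (mean, sd) in published.items():
            ages = table1.loc[table1.group == group, "age"]
            assert round(float(ages.mean()), 2) == mean
            assert round(float(ages.std(ddof=1)), 2) == sd


class TestSimulate:
    def test_zero_model_returns_exact_baseline(self, atlas, table1, basis7):
        baseline = 2.7 + 0.1 * np.sin(np.arange(68))
        truth = cs.GroundTruth(
            coefficients=np.vstack([baseline, np.zeros((4, 68))]),
            covariate_names=("intercept", "age", "sex_male", "LTLE", "RTLE"),
            sigma_re=np.zeros((9, 9)),
            matern=cs.MaternParams(0.0, 0.0, 1.0, 1.0),
            J=9,
            seed=0,
        )
        ds = cs.simulate_thickness(atlas, table1, truth, basis7)
        np.testing.assert_array_equal(
            ds.thickness.to_numpy(), np.tile(baseline, (53, 1))
        )

    def test_doubling_a_coefficient_doubles_the_group_contrast(
        self, atlas, table1, basis7
    ):
        def run(scale):
            effect = -0.2 * np.exp(-np.linspace(0, 3, 68))
            truth = cs.GroundTruth(
                coefficients=np.vstack(
                    [np.full(68, 2.7), np.zeros((2, 68)), scale * effect, np.zeros(68)]
                ),
                covariate_names=("intercept", "age", "sex_male", "LTLE", "RTLE"),
                sigma_re=np.zeros((9, 9)),
                matern=cs.MaternParams(0.0, 0.0, 1.0, 1.0),
                J=9,
                seed=0,
            )
            ds = cs.simulate_thickness(atlas, table1, truth, basis7)
            g = ds.cohort.group.to_numpy()
            vals = ds.thickness.to_numpy()
            return vals[g == "LTLE"].mean(axis=0) - vals[g == "HC"].mean(axis=0)

        np.testing.assert_allclose(run(2.0), 2.0 * run(1.0), atol=1e-12)

    def test_identical_seeds_give_identical_datasets(self, atlas, table1, truth, basis7):
        a = cs.simulate_thickness(atlas, table1, truth, basis7)
        b = cs.simulate_thickness(atlas, table1, truth, basis7)
        pd.testing.assert_frame_equal(a.thickness, b.thickness)

    def test_residual_covariance_and_marginal_variance_oracle(self, atlas, basis7):
        """Empirical moments over 20,000 replicate subjects match the model:
        residual covariance equals the nugget+Matérn matrix and the marginal
        variance adds the random-effect contribution sum_j Z_j(v)^2 Sigma_jj."""
        m = 20_000
        cohort = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(m)],
                "group": "HC",
                "age": 30.0,
                "sex": "M",
            }
        )
        params = cs.MaternParams(0.07**2, 0.14**2, 0.5, 1.0)
        J = 4
        sigma_re = np.diag([0.08**2, 0.06**2, 0.05**2, 0.04**2])
        truth = cs.GroundTruth(
            coefficients=np.vstack([np.full(68, 2.7), np.zeros((4, 68))]),
            covariate_names=("intercept", "age", "sex_male", "LTLE", "RTLE"),
            sigma_re=sigma_re,
            matern=params,
            J=J,
            seed=42,
        )
        ds = cs.simulate_thickness(atlas, cohort, truth, basis7)
        points = ds.points
        resid = ds.thickness.to_numpy() - 2.7
        emp = resid.T @ resid / m - np.outer(resid.mean(0), resid.mean(0))

        cov = cs.covariance_matrix(points, params)
        Z = basis7.matrix[:, :J]
        analytic = cov + Z @ sigma_re @ Z.T
        se = np.sqrt(
            (np.outer(np.diag(analytic), np.diag(analytic)) + analytic**2) / m
        )
        z = np.abs(emp - analytic) / se
        iu = np.triu_indices(68)
        # entrywise MC agreement, multiplicity-aware over 2346 entries
        assert np.mean(z[iu] <= 3.0) >= 0.99
        assert z.max() < 5.0

        # spot-check the marginal variance decomposition at three regions
        for v in (0, 30, 67):
            expect = params.total_variance + float(Z[v] @ sigma_re @ Z[v])
            assert emp[v, v] == pytest.approx(expect, rel=0.08)

    def test_inconsistent_dimensions_raise(self, atlas, table1, basis7):
        truth = cs.GroundTruth(
            coefficients=np.zeros((5, 10)),
            covariate_names=("intercept", "age", "sex_male", "LTLE", "RTLE"),
            sigma_re=np.eye(9) * 0.01,
            matern=cs.MaternParams(0.01, 0.01, 0.5, 1.0),
            J=9,
            seed=0,
        )
        with pytest.raises(ValueError):
            cs.simulate_thickness(atlas, table1, truth, basis7)


def test_dataset_validation_rejects_bad_values(atlas, table1):
    thick = pd.DataFrame(
        np.full((53, 68), 2.5),
        index=list(table1["subject_id"]),
        columns=list(atlas["region_name"]),
    )
    thick.iloc[2, 3] = -1.0
    with pytest.raises(ValueError, match="positive"):
        cs.ThicknessDataset(thickness=thick, cohort=table1, atlas=atlas)
    thick.iloc[2, 3] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        cs.ThicknessDataset(thickness=thick, cohort=table1, atlas=atlas)
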