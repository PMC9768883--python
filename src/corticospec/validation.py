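"""Reproducibility experiments validating the pipeline end to end.

Each function builds its own synthetic inputs at study scale, runs the
relevant part of the package, and returns the measured quantities: the
published demographic statistics recomputed from the cohort fixture, the
spectral dimension at the published truncation, a Gibbs-versus-closed-form
gap, credible-interval coverage and Bayesian-FDR calibration over replicate
simulated cohorts, a Matérn sampling check, the transform round-trip error,
and classifier sanity values.  Problem sizes are chosen so the whole battery
runs on a single CPU in minutes; every function is deterministic given its
seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import MlpSpec, mlp_loocv_scores, roc_auc
from .cohort import GroundTruth, default_truth, make_atlas, simulate_thickness, table1_fixture
from .demographics import age_summaries, anova_from_summary, chisq_homogeneity, sex_contingency
from .fdr import bayesian_fdr_threshold, null_probabilities
from .harmonics import SphericalPoint, build_basis, forward_sht, inverse_sht
from .matern import MaternParams, covariance_matrix, spectral_density
from .model import ModelConfig, fit_thickness_model, run_mcmc, spatial_coefficient_draws

__all__ = [
    "demographic_checks",
    "spectral_dimension",
    "gibbs_closed_form_gap",
    "coverage_experiment",
    "fdr_calibration",
    "matern_sampling_gap",
    "sht_roundtrip_error",
    "classifier_checks",
]


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % 2**31)


def demographic_checks() -> dict:
    """Chi-square, ANOVA and pooled age moments from the published margins.

    The sex test uses the group x sex counts directly; the ANOVA and the
    overall mean/SD are recomputed from the per-group (n, mean, sd)
    summaries of the cohort fixture.
    """
    cohort = table1_fixture()
    stat, df, _ = chisq_homogeneity(sex_contingency(cohort))
    groups = age_summaries(cohort)
    F, df1, df2, _ = anova_from_summary(groups)
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    N = ns.sum()
    grand = float(np.sum(ns * means) / N)
    ss_total = float(np.sum((ns - 1) * sds**2) + np.sum(ns * (means - grand) ** 2))
    overall_sd = float(np.sqrt(ss_total / (N - 1)))
    return {
        "sex_chisq": float(stat),
        "sex_chisq_df": int(df),
        "age_anova_f": float(F),
        "age_anova_df": (int(df1), int(df2)),
        "age_mean_overall": grand,
        "age_sd_overall": overall_sd,
        "n_subjects": int(N),
    }


def spectral_dimension(L: int = 7, seed: int = 0) -> int:
    """Number of real spectral terms for the 68-region atlas at degree ``L``."""
    atlas = make_atlas(seed)
    points = [SphericalPoint(r.colatitude_rad, r.longitude_rad) for r in atlas.itertuples()]
    return build_basis(points, L).n_columns


def gibbs_closed_form_gap(seed: int = 0) -> dict:
    """Sampler-vs-conjugate-closed-form gap for the fully tractable model.

    With independent residuals, Gaussian fixed-effect prior, no
    nonstationary terms and all three variance blocks frozen, the posterior
    of every spectral coefficient vector is a known multivariate normal per
    column; the retained draws are then iid from it, so the Monte-Carlo
    standard error of each posterior mean is exactly sd/sqrt(draws).
    Returns the largest standardised deviation over 16 columns x 3
    covariates at m = 20 subjects.
    """
    rng = np.random.default_rng(_child_seed(seed, 3))
    atlas = make_atlas(0)
    points = [SphericalPoint(r.colatitude_rad, r.longitude_rad) for r in atlas.itertuples()]
    basis = build_basis(points, 3)  # 16 spectral coefficients
    m, q = 20, 3
    X = np.column_stack([np.ones(m), rng.normal(size=(m, 2))])
    y_spec = rng.normal(size=(m, basis.n_columns))
    fix_res = MaternParams(0.5, 0.0, 1.0, 1.0)
    fix0 = MaternParams(0.3, 0.7, 0.5, 1.0)
    fix1 = MaternParams(0.2, 0.3, 0.8, 0.7)
    config = ModelConfig(
        residual="independent", fe_prior="gaussian", nonstationary=False,
        J=4, L=3, iterations=4500, burn_in=500, thinning=1,
        seed=_child_seed(seed, 30),
        fixed_residual=fix_res, fixed_intercept_process=fix0,
        fixed_slope_process=fix1,
    )
    samples = run_mcmc(y_spec, X, basis, config)
    degrees = basis.degrees
    lam0 = spectral_density(degrees, fix0)
    lam1 = spectral_density(degrees, fix1)
    # independent residuals propagate the nugget through the transform
    pinv = np.linalg.pinv(basis.matrix)
    lam_res = fix_res.total_variance * np.einsum("wi,wi->w", pinv, pinv)
    XtX = X.T @ X
    max_z = 0.0
    for w in range(basis.n_columns):
        lam_prior = np.array([lam0[w], lam1[w], lam1[w]])
        prec = XtX / lam_res[w] + np.diag(1.0 / lam_prior)
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ y_spec[:, w] / lam_res[w])
        mc_mean = samples.b_tilde[:, :, w].mean(axis=0)
        mcse = np.sqrt(np.diag(cov) / samples.n_retained)
        max_z = max(max_z, float(np.max(np.abs(mc_mean - mean) / mcse)))
    return {"max_abs_z": max_z, "n": samples.n_retained}


def _two_group_cohort(rng: np.random.Generator, n_hc: int, n_pat: int) -> pd.DataFrame:
    rows = []
    for i in range(n_hc):
        rows.append({"subject_id": f"H{i:03d}", "group": "HC",
                     "age": float(rng.normal(28, 6)), "sex": "M" if i % 2 else "F"})
    for i in range(n_pat):
        rows.append({"subject_id": f"P{i:03d}", "group": "LTLE",
                     "age": float(rng.normal(32, 8)), "sex": "M" if i % 3 else "F"})
    return pd.DataFrame(rows)


def coverage_experiment(
    n_replicates: int = 50,
    seed: int = 0,
    n_hc: int = 20,
    n_pat: int = 20,
    iterations: int = 2000,
    burn_in: int = 500,
    thinning: int = 5,
    group_effect: float = -0.15,
) -> dict:
    """Frequentist coverage of 90% credible intervals for the group-effect surface.

    Each replicate simulates a two-group cohort (m = n_hc + n_pat) with a
    known negative patient effect over 68 regions, fits the selected model
    (Matérn residuals, Gaussian fixed effects, nonstationary, J = 9, L = 7)
    on a desk-scale schedule, and records the fraction of regions whose
    true effect lies inside the central 90% interval.
    """
    atlas = make_atlas(0)
    points = [SphericalPoint(r.colatitude_rad, r.longitude_rad) for r in atlas.itertuples()]
    basis = build_basis(points, 7)
    coverages = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(_child_seed(seed, 4, rep))
        cohort = _two_group_cohort(rng, n_hc, n_pat)
        truth = default_truth(
            atlas, J=9, L=7, seed=_child_seed(seed, 40, rep), group_effect=group_effect
        )
        ds = simulate_thickness(atlas, cohort, truth, basis)
        config = ModelConfig(
            residual="matern", fe_prior="gaussian", nonstationary=True, J=9, L=7,
            iterations=iterations, burn_in=burn_in, thinning=thinning,
            seed=_child_seed(seed, 41, rep),
        )
        samples = fit_thickness_model(ds, config)
        draws = spatial_coefficient_draws(samples)
        k = list(samples.covariate_names).index("LTLE")
        lo, hi = np.percentile(draws[:, k, :], [5.0, 95.0], axis=0)
        true_effect = truth.coefficients[3]
        coverages.append(float(np.mean((true_effect >= lo) & (true_effect <= hi))))
    coverages = np.array(coverages)
    return {
        "mean_coverage": float(coverages.mean()),
        "se": float(coverages.std(ddof=1) / np.sqrt(n_replicates)),
        "per_replicate": coverages,
        "n": n_replicates,
    }


def fdr_calibration(
    n_replicates: int = 50,
    seed: int = 0,
    q: float = 0.01,
    n_hc: int = 15,
    n_pat: int = 15,
    iterations: int = 2000,
    burn_in: int = 750,
    thinning: int = 5,
) -> dict:
    """False rejections of the Bayesian-FDR rule on null simulated cohorts.

    Group effects are identically zero, so every rejection is false.
    Reports the mean false-rejection rate (falsely rejected regions out of
    68) and the mean false-discovery proportion among rejected regions
    (1 whenever anything is rejected on null data, else 0).
    """
    atlas = make_atlas(0)
    points = [SphericalPoint(r.colatitude_rad, r.longitude_rad) for r in atlas.itertuples()]
    basis = build_basis(points, 7)
    n_regions = len(points)
    rates, fdps = [], []
    for rep in range(n_replicates):
        rng = np.random.default_rng(_child_seed(seed, 5, rep))
        cohort = _two_group_cohort(rng, n_hc, n_pat)
        base = default_truth(atlas, J=9, L=7, seed=_child_seed(seed, 50, rep))
        truth = GroundTruth(
            coefficients=np.vstack([base.coefficients[:3], np.zeros((2, n_regions))]),
            covariate_names=base.covariate_names,
            sigma_re=base.sigma_re,
            matern=base.matern,
            J=base.J,
            seed=base.seed,
        )
        ds = simulate_thickness(atlas, cohort, truth, basis)
        config = ModelConfig(
            residual="matern", fe_prior="gaussian", nonstationary=True, J=9, L=7,
            iterations=iterations, burn_in=burn_in, thinning=thinning,
            seed=_child_seed(seed, 51, rep),
        )
        samples = fit_thickness_model(ds, config)
        draws = spatial_coefficient_draws(samples)
        k = list(samples.covariate_names).index("LTLE")
        result = bayesian_fdr_threshold(null_probabilities(draws[:, k, :]), q)
        rates.append(result.n_rejected / n_regions)
        fdps.append(1.0 if result.n_rejected else 0.0)
    rates = np.array(rates)
    fdps = np.array(fdps)
    return {
        "mean_false_rejection_rate": float(rates.mean()),
        "se_rate": float(rates.std(ddof=1) / np.sqrt(n_replicates)),
        "mean_fdp": float(fdps.mean()),
        "se_fdp": float(fdps.std(ddof=1) / np.sqrt(n_replicates)),
        "q": q,
        "n": n_replicates,
    }


def matern_sampling_gap(
    n_draws: int = 20_000, n_points: int = 30, seed: int = 0
) -> dict:
    """Empirical-vs-analytic covariance gap for fields drawn from the Matérn model.

    Draws ``n_draws`` zero-mean fields at ``n_points`` random sphere
    locations from the Cholesky factor of the nugget + Matérn covariance and
    standardises each empirical covariance entry by its Monte-Carlo standard
    error sqrt((C_ii C_jj + C_ij^2)/n).  Returns the largest standardised
    deviation over the 465 unique entries.
    """
    rng = np.random.default_rng(_child_seed(seed, 6))
    u = rng.uniform(-1.0, 1.0, size=n_points)
    lon = rng.uniform(0.0, 2.0 * np.pi, size=n_points)
    points = [SphericalPoint(float(np.arccos(c)), float(t)) for c, t in zip(u, lon)]
    params = MaternParams(sigma2=0.3, tau2=0.7, range_=0.6, smoothness=1.2)
    cov = covariance_matrix(points, params)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_points))
    draws = rng.standard_normal((n_draws, n_points)) @ chol.T
    emp = draws.T @ draws / n_draws
    se = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov**2) / n_draws)
    z = np.abs(emp - cov) / se
    iu = np.triu_indices(n_points)
    return {
        "max_abs_z": float(z.max()),
        "frac_within_3se": float(np.mean(z[iu] <= 3.0)),
        "n": n_draws,
    }


def sht_roundtrip_error(n_points: int = 64, L: int = 7, seed: int = 0) -> float:
    """Max absolute coefficient error of forward-after-inverse at general-position points."""
    rng = np.random.default_rng(_child_seed(seed, 7))
    u = rng.uniform(-1.0, 1.0, size=n_points)
    lon = rng.uniform(0.0, 2.0 * np.pi, size=n_points)
    points = [SphericalPoint(float(np.arccos(c)), float(t)) for c, t in zip(u, lon)]
    basis = build_basis(points, L)
    coeffs = rng.normal(size=basis.n_columns)
    recovered = forward_sht(inverse_sht(coeffs, basis), basis)
    return float(np.max(np.abs(recovered - coeffs)))


def classifier_checks(seed: int = 0, n_permutations: int = 20) -> dict:
    """AUC hand check, permutation null, and LOOCV determinism.

    The six-point AUC has the exact value 7/9 by enumerating all nine
    positive-negative score pairs; label-permuted data should give mean
    LOOCV AUC near one half; and repeated runs with the same seed must give
    identical held-out scores.
    """
    auc_six = roc_auc(np.array([1, 2, 3, 4, 5, 6.0]), np.array([0, 1, 0, 1, 0, 1])).auc

    rng = np.random.default_rng(_child_seed(seed, 8))
    spec = MlpSpec(hidden_units=3, max_epochs=300, seed=_child_seed(seed, 80))
    aucs = []
    n = 24
    for _ in range(n_permutations):
        feats = rng.normal(size=(n, 3))
        labels = rng.permutation(np.repeat([0, 1], n // 2))
        scores = mlp_loocv_scores(feats, labels, spec)
        aucs.append(roc_auc(scores, labels).auc)
    feats = rng.normal(size=(n, 3))
    labels = np.repeat([0, 1], n // 2)
    s1 = mlp_loocv_scores(feats, labels, spec)
    s2 = mlp_loocv_scores(feats, labels, spec)
    return {
        "auc_six_point": float(auc_six),
        "permutation_null_mean_auc": float(np.mean(aucs)),
        "n_permutations": n_permutations,
        "deterministic": bool(np.array_equal(s1, s2)),
    }
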