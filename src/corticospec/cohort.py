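"""Synthetic cohorts: atlas, demographics and thickness fields with ground truth.

The generator emulates a region-level cortical-thickness study: 68
Desikan-style regions (34 per hemisphere) with unit-sphere centroids, a
three-group cohort (healthy controls plus left/right temporal-lobe-epilepsy
patients, 20/19/14 subjects with the published age and sex margins), and
thickness fields built from the additive spatial model

    Y_i(v) = sum_k X_ik B_k(v) + sum_j Z_j(v) gamma_ij + E_i(v)

with spatially varying fixed-effect surfaces B_k, subject random effects
gamma_i ~ N(0, Sigma) on the first J harmonic basis functions Z_j, and a
nugget + Matérn residual E_i.  Ground truth is retained so estimation and
coverage can be checked against it.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .harmonics import HarmonicBasis, SphericalPoint, build_basis
from .matern import MaternParams, covariance_matrix

__all__ = [
    "DESIKAN_BASE_NAMES",
    "GroundTruth",
    "ThicknessDataset",
    "make_atlas",
    "table1_fixture",
    "design_matrix",
    "default_truth",
    "simulate_thickness",
]

#: the 34 region names of the Desikan cortical parcellation (one hemisphere).
DESIKAN_BASE_NAMES = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

GROUPS = ("HC", "LTLE", "RTLE")

#: published group sizes, sex counts (M, F) and age mean/SD per group.
TABLE1_SUMMARY = {
    "HC": {"n": 20, "males": 10, "age_mean": 27.95, "age_sd": 6.32},
    "LTLE": {"n": 19, "males": 11, "age_mean": 32.10, "age_sd": 8.47},
    "RTLE": {"n": 14, "males": 10, "age_mean": 28.28, "age_sd": 6.28},
}

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """True generative quantities kept for recovery tests.

    coefficients : ndarray, shape (n_covariates, n_regions)
        Rows follow the design-matrix column order of :func:`design_matrix`
        (intercept, centred age, male sex, LTLE, RTLE); mm per covariate unit.
    covariate_names : tuple of str
    sigma_re : ndarray, shape (J, J)
        Random-effect covariance Sigma (symmetric positive definite).
    matern : MaternParams
        Residual nugget + Matérn parameters.
    J : int
    seed : int
    """

    coefficients: np.ndarray
    covariate_names: tuple[str, ...]
    sigma_re: np.ndarray
    matern: MaternParams
    J: int
    seed: int

    def __post_init__(self) -> None:
        S = np.asarray(self.sigma_re)
        if S.shape != (self.J, self.J) or not np.allclose(S, S.T):
            raise ValueError("Sigma must be symmetric with shape (J, J)")
        if self.J > 0 and np.linalg.eigvalsh(S).min() < -1e-12:
            raise ValueError("Sigma must be positive semi-definite")


@dataclasses.dataclass
class ThicknessDataset:
    """Subjects x regions thickness (mm) joined with cohort and atlas tables.

    thickness : DataFrame indexed by subject id, one column per region.
    cohort : DataFrame with columns subject_id, group, age, sex.
    atlas : DataFrame with columns region_name, hemisphere, colatitude_rad,
        longitude_rad.
    """

    thickness: pd.DataFrame
    cohort: pd.DataFrame
    atlas: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.thickness.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                "thickness contains a non-finite value at subject "
                f"'{self.thickness.index[bad[0]]}', region "
                f"'{self.thickness.columns[bad[1]]}'"
            )
        if np.any(vals <= 0):
            bad = np.argwhere(vals <= 0)[0]
            raise ValueError(
                "thickness must be positive; offending cell: subject "
                f"'{self.thickness.index[bad[0]]}', region "
                f"'{self.thickness.columns[bad[1]]}'"
            )
        if list(self.thickness.index) != list(self.cohort["subject_id"]):
            raise ValueError("thickness rows do not align with the cohort table")
        if list(self.thickness.columns) != list(self.atlas["region_name"]):
            raise ValueError("thickness columns do not align with the atlas table")

    @property
    def points(self) -> list[SphericalPoint]:
        return [
            SphericalPoint(row.colatitude_rad, row.longitude_rad)
            for row in self.atlas.itertuples()
        ]

    @property
    def n_subjects(self) -> int:
        return self.thickness.shape[0]

    @property
    def n_regions(self) -> int:
        return self.thickness.shape[1]


def make_atlas(seed: int = 0) -> pd.DataFrame:
    """68 quasi-uniform centroids, 34 per hemisphere, on a single unit sphere.

    Left-hemisphere centroids occupy longitudes [0, pi) and right-hemisphere
    centroids [pi, 2*pi); within each half the points follow a Fibonacci
    lattice with a small seeded jitter, so the atlas is deterministic given
    the seed and the minimum pairwise chordal distance stays comfortably
    above 0.05.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for hemi, suffix, lon_offset in (("L", "lh", 0.0), ("R", "rh", np.pi)):
        n = len(DESIKAN_BASE_NAMES)
        for i, name in enumerate(DESIKAN_BASE_NAMES):
            z = 1.0 - 2.0 * (i + 0.5) / n
            colat = float(np.arccos(np.clip(z, -1.0, 1.0)))
            lon = float((i * _GOLDEN_ANGLE) % np.pi) + lon_offset
            colat = float(np.clip(colat + rng.normal(0.0, 0.01), 1e-3, np.pi - 1e-3))
            jitter = rng.normal(0.0, 0.01)
            lon = float(np.clip(lon + jitter, lon_offset, lon_offset + np.pi - 1e-9))
            rows.append(
                {
                    "region_name": f"{name}_{suffix}",
                    "hemisphere": hemi,
                    "colatitude_rad": colat,
                    "longitude_rad": lon,
                }
            )
    return pd.DataFrame(rows)


def table1_fixture() -> pd.DataFrame:
    """Deterministic 53-subject cohort matching the published demographics.

    Group sizes 20/19/14 with sex counts 10/10, 11/8 and 10/4; ages are drawn
    once from group-specific normals (fixed internal seed) and affinely
    adjusted so each group's sample mean and SD equal the published values
    exactly, which reproduces the printed chi-square (1.56, df 2) and ANOVA
    (F = 1.92, df 2 and 50) statistics.
    """
    rng = np.random.default_rng(20221221)
    rows = []
    counter = 1
    for group in GROUPS:
        info = TABLE1_SUMMARY[group]
        n, males = info["n"], info["males"]
        ages = rng.normal(info["age_mean"], info["age_sd"], size=n)
        ages = (ages - ages.mean()) / ages.std(ddof=1)
        ages = info["age_mean"] + info["age_sd"] * ages
        sexes = ["M"] * males + ["F"] * (n - males)
        for age, sex in zip(ages, sexes):
            rows.append(
                {
                    "subject_id": f"S{counter:03d}",
                    "group": group,
                    "age": float(age),
                    "sex": sex,
                }
            )
            counter += 1
    return pd.DataFrame(rows)


def design_matrix(
    cohort: pd.DataFrame, age_center: float | None = None
) -> tuple[np.ndarray, tuple[str, ...], float]:
    """Fixed-effect design: intercept, centred age, male sex, LTLE/RTLE dummies.

    Healthy controls are the baseline group.  ``age_center`` defaults to the
    sample mean and is returned so held-out subjects can reuse the training
    centring.
    """
    if age_center is None:
        age_center = float(cohort["age"].mean())
    X = np.column_stack(
        [
            np.ones(len(cohort)),
            cohort["age"].to_numpy(dtype=float) - age_center,
            (cohort["sex"] == "M").to_numpy(dtype=float),
            (cohort["group"] == "LTLE").to_numpy(dtype=float),
            (cohort["group"] == "RTLE").to_numpy(dtype=float),
        ]
    )
    names = ("intercept", "age", "sex_male", "LTLE", "RTLE")
    return X, names, age_center


def _smooth_field(basis: HarmonicBasis, rng: np.random.Generator,
                  scale: float, max_degree: int) -> np.ndarray:
    """A smooth random surface from low-degree harmonic coefficients."""
    coeffs = np.zeros(basis.n_columns)
    degrees = basis.degrees
    use = degrees <= max_degree
    coeffs[use] = rng.normal(0.0, scale, size=int(use.sum())) / (1.0 + degrees[use])
    return basis.matrix @ coeffs


def default_truth(
    atlas: pd.DataFrame,
    J: int = 9,
    L: int = 7,
    seed: int = 1234,
    group_effect: float = -0.15,
) -> GroundTruth:
    """Study-scale ground truth for the synthetic cohort.

    Baseline surface around 2.7 mm with smooth low-degree variation; a small
    smooth negative age slope (about -0.01 mm/year); a near-zero sex effect;
    an LTLE effect that is a smooth negative surface deepest (``group_effect``
    mm) over a block of cingulate/frontal regions; an RTLE effect
    concentrated on the right entorhinal area.  Residuals: nugget sd 0.07 mm,
    Matérn sd 0.14 mm, range 0.5, smoothness 1; random-effect covariance
    Sigma diagonal, sd 0.05 on the first J harmonic columns.
    """
    rng = np.random.default_rng(seed)
    points = [
        SphericalPoint(r.colatitude_rad, r.longitude_rad) for r in atlas.itertuples()
    ]
    basis = build_basis(points, L)
    n = len(points)

    baseline = 2.7 + _smooth_field(basis, rng, scale=0.25, max_degree=2)
    age = -0.01 + 0.004 * _smooth_field(basis, rng, scale=1.0, max_degree=2)
    sex = 0.01 + 0.004 * _smooth_field(basis, rng, scale=1.0, max_degree=1)

    names = list(atlas["region_name"])
    ltle_targets = [
        i
        for i, name in enumerate(names)
        if any(
            key in name
            for key in (
                "caudalanteriorcingulate",
                "rostralanteriorcingulate",
                "superiorfrontal",
                "lateralorbitofrontal_lh",
                "frontalpole_lh",
                "temporalpole_lh",
            )
        )
    ]
    rtle_targets = [i for i, name in enumerate(names) if name == "entorhinal_rh"]

    def _bump(targets: Sequence[int], depth: float) -> np.ndarray:
        """Smooth negative surface peaking at the target centroids."""
        field = np.zeros(n)
        vecs = np.array([p.unit_vector() for p in points])
        for t in targets:
            d2 = np.sum((vecs - vecs[t]) ** 2, axis=1)
            field += depth * np.exp(-d2 / 0.35)
        peak = np.min(field)
        if peak < 0:
            field *= depth / peak
        return field

    ltle = _bump(ltle_targets, group_effect)
    rtle = _bump(rtle_targets, group_effect * 0.8)

    coefficients = np.vstack([baseline, age, sex, ltle, rtle])
    sigma_re = np.diag(np.full(J, 0.05**2))
    matern = MaternParams(sigma2=0.07**2, tau2=0.14**2, range_=0.5, smoothness=1.0)
    return GroundTruth(
        coefficients=coefficients,
        covariate_names=("intercept", "age", "sex_male", "LTLE", "RTLE"),
        sigma_re=sigma_re,
        matern=matern,
        J=J,
        seed=seed,
    )


def simulate_thickness(
    atlas: pd.DataFrame,
    cohort: pd.DataFrame,
    truth: GroundTruth,
    basis: HarmonicBasis,
) -> ThicknessDataset:
    """Draw a thickness dataset from the additive spatial model.

    Deterministic given ``truth.seed``: fixed part X B, random effects
    gamma_i ~ N(0, Sigma) on the first J basis columns, residuals from the
    nugget + Matérn covariance (skipped when the total variance is zero).
    """
    n_regions = len(atlas)
    if basis.n_points != n_regions:
        raise ValueError("basis points do not match the atlas")
    if truth.coefficients.shape != (5, n_regions):
        raise ValueError(
            f"truth coefficients shape {truth.coefficients.shape} "
            f"inconsistent with {n_regions} regions"
        )
    if truth.J > basis.n_columns:
        raise ValueError("truth J exceeds the number of basis columns")

    rng = np.random.default_rng(truth.seed)
    X, _, _ = design_matrix(cohort)
    m = X.shape[0]
    Y = X @ truth.coefficients

    if truth.J > 0 and np.any(truth.sigma_re):
        gammas = rng.multivariate_normal(
            np.zeros(truth.J), truth.sigma_re, size=m, method="cholesky"
        )
        Y = Y + gammas @ basis.matrix[:, : truth.J].T

    if truth.matern.total_variance > 0:
        points = [
            SphericalPoint(r.colatitude_rad, r.longitude_rad)
            for r in atlas.itertuples()
        ]
        cov = covariance_matrix(points, truth.matern)
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_regions))
        Y = Y + rng.standard_normal((m, n_regions)) @ chol.T

    thickness = pd.DataFrame(
        Y, index=list(cohort["subject_id"]), columns=list(atlas["region_name"])
    )
    return ThicknessDataset(
        thickness=thickness, cohort=cohort.reset_index(drop=True), atlas=atlas
    )
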