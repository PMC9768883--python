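"""Leave-one-out cross-validated model comparison over the 16-configuration grid.

Each candidate model is scored by the mean squared error of its posterior
predictive mean for the held-out subject's regional thickness values,
averaged over subjects and regions.  The grid crosses residual structure
(independent / Matérn), fixed-effect prior (Gaussian / horseshoe), the
nonstationary random-effect component (off / on) and the basis count
J in {4, 9}, in that nesting order.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import ThicknessDataset, design_matrix
from .harmonics import build_basis
from .model import ModelConfig, run_mcmc, transform_dataset

__all__ = ["config_grid", "loocv_mse", "evaluate_grid", "select_best"]

#: (residual, fe_prior, nonstationary, J) in published row order.
_GRID_AXES = [
    (residual, fe, nonstat, J)
    for residual in ("independent", "matern")
    for fe in ("gaussian", "horseshoe")
    for nonstat in (False, True)
    for J in (4, 9)
]


def config_grid(base: ModelConfig) -> list[ModelConfig]:
    """The 16 candidate configurations, varying structure around ``base``."""
    return [
        dataclasses.replace(
            base, residual=residual, fe_prior=fe, nonstationary=nonstat, J=J
        )
        for residual, fe, nonstat, J in _GRID_AXES
    ]


def _bayes_predictor(config: ModelConfig) -> Callable:
    """Posterior-predictive-mean predictor for one held-out subject.

    The held-out prediction uses the subject's covariates with the
    posterior mean of the coefficient surfaces; random effects enter at
    their prior mean (zero), so no subject-specific information leaks.
    """

    def predict(train: ThicknessDataset, holdout_row: pd.Series, fold: int) -> np.ndarray:
        basis = build_basis(train.points, config.L)
        spectral = transform_dataset(train, basis)
        X, names, age_center = design_matrix(train.cohort)
        fold_config = dataclasses.replace(config, seed=int((config.seed + 104729 * (fold + 1)) % 2**31))
        samples = run_mcmc(
            spectral.matrix, X, basis, fold_config,
            covariate_names=names, region_names=spectral.region_names,
        )
        b_mean = samples.b_tilde.mean(axis=0)  # (q, columns)
        x_hold = np.array(
            [
                1.0,
                float(holdout_row["age"]) - age_center,
                1.0 if holdout_row["sex"] == "M" else 0.0,
                1.0 if holdout_row["group"] == "LTLE" else 0.0,
                1.0 if holdout_row["group"] == "RTLE" else 0.0,
            ]
        )
        return basis.matrix @ (x_hold @ b_mean)

    return predict


def loocv_mse(
    ds: ThicknessDataset,
    config: ModelConfig,
    predictor: Callable | None = None,
) -> float:
    """Grand-mean squared prediction error over subjects x regions.

    ``predictor(train_dataset, holdout_cohort_row, fold_index)`` must return
    the predicted regional values for the held-out subject; the default is
    the Bayesian posterior predictive mean under ``config``.  Invariant to
    subject ordering.  A failing fold raises an error naming the subject.
    """
    if ds.n_subjects < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    predict = predictor if predictor is not None else _bayes_predictor(config)
    sq_errors = []
    for fold, sid in enumerate(ds.thickness.index):
        mask = ds.cohort["subject_id"] != sid
        train = ThicknessDataset(
            thickness=ds.thickness.loc[mask.to_numpy()],
            cohort=ds.cohort.loc[mask].reset_index(drop=True),
            atlas=ds.atlas,
        )
        holdout_row = ds.cohort.loc[ds.cohort["subject_id"] == sid].iloc[0]
        try:
            yhat = np.asarray(predict(train, holdout_row, fold), dtype=float)
        except Exception as exc:  # noqa: BLE001 - re-raise with fold context
            raise RuntimeError(f"LOOCV fold for subject '{sid}' failed: {exc}") from exc
        y = ds.thickness.loc[sid].to_numpy(dtype=float)
        if yhat.shape != y.shape:
            raise RuntimeError(f"LOOCV fold for subject '{sid}' returned a bad shape")
        sq_errors.append((y - yhat) ** 2)
    return float(np.mean(sq_errors))


def evaluate_grid(
    ds: ThicknessDataset, grid: Sequence[ModelConfig]
) -> pd.DataFrame:
    """LOOCV MSE for every configuration; rows in grid order."""
    rows = []
    for cfg in grid:
        rows.append(
            {
                "residual": cfg.residual,
                "fe_prior": cfg.fe_prior,
                "nonstationary": cfg.nonstationary,
                "J": cfg.J,
                "mse": loocv_mse(ds, cfg),
            }
        )
    return pd.DataFrame(rows)


def select_best(
    results: pd.DataFrame | Sequence[tuple[ModelConfig, float]],
    grid: Sequence[ModelConfig] | None = None,
) -> ModelConfig:
    """Arg-min MSE configuration; ties broken by grid order.

    Accepts either the DataFrame from :func:`evaluate_grid` together with
    the grid, or a sequence of (config, mse) pairs.
    """
    if isinstance(results, pd.DataFrame):
        if grid is None:
            raise ValueError("pass the grid alongside the results DataFrame")
        mses = results["mse"].to_numpy(dtype=float)
        configs = list(grid)
    else:
        pairs = list(results)
        if not pairs:
            raise ValueError("no results to select from")
        configs = [c for c, _ in pairs]
        mses = np.array([m for _, m in pairs], dtype=float)
    return configs[int(np.argmin(mses))]
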