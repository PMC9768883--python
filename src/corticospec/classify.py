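"""Classification benchmark: region selection, MLP under LOOCV, and ROC/AUC.

Two routes produce candidate region sets for discriminating patient groups:
the Bayesian FDR map, and a classical region-by-region linear regression
(thickness on group, age and sex; regions with a negative group coefficient
at two-sided p < 0.05 are selected).  A small multilayer perceptron with a
logistic hidden layer and linear output is then scored by leave-one-out
cross-validation, and the pooled held-out scores give one ROC curve per
contrast.  The AUC is the Mann–Whitney probability over positive-negative
pairs with ties counted one half.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.neural_network import MLPRegressor

from .cohort import ThicknessDataset

__all__ = ["MlpSpec", "RocCurve", "regionwise_glm", "mlp_loocv_scores", "roc_auc"]


@dataclasses.dataclass(frozen=True)
class MlpSpec:
    """One-hidden-layer perceptron: logistic hidden units, linear output."""

    hidden_units: int = 3
    max_epochs: int = 500
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("need at least one hidden unit")


@dataclasses.dataclass(frozen=True)
class RocCurve:
    """ROC curve points (endpoints (0,0) and (1,1)) and its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def regionwise_glm(
    ds: ThicknessDataset, contrast: tuple[str, str] = ("HC", "LTLE")
) -> pd.DataFrame:
    """Region-by-region OLS of thickness on group + age + sex.

    ``contrast`` names (baseline, patient) groups; the returned frame has one
    row per region with the patient-group coefficient, its two-sided p-value
    and a ``selected`` flag (negative coefficient and p < 0.05).
    """
    base, target = contrast
    present = set(ds.cohort["group"])
    if base not in present or target not in present:
        raise ValueError(f"contrast groups {contrast} not both present")
    mask = ds.cohort["group"].isin(contrast).to_numpy()
    cohort = ds.cohort.loc[mask]
    thick = ds.thickness.loc[mask]
    design = np.column_stack(
        [
            np.ones(mask.sum()),
            (cohort["group"] == target).to_numpy(dtype=float),
            cohort["age"].to_numpy(dtype=float),
            (cohort["sex"] == "M").to_numpy(dtype=float),
        ]
    )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("singular design matrix (a covariate is constant)")
    rows = []
    for region in thick.columns:
        y = thick[region].to_numpy(dtype=float)
        if np.var(y) == 0:
            raise ValueError(f"degenerate fit: region '{region}' has zero variance")
        fit = sm.OLS(y, design).fit()
        coef, p = float(fit.params[1]), float(fit.pvalues[1])
        rows.append(
            {
                "region": region,
                "coef": coef,
                "pvalue": p,
                "selected": bool(coef < 0 and p < 0.05),
            }
        )
    return pd.DataFrame(rows)


def mlp_loocv_scores(
    features: np.ndarray, labels: np.ndarray, spec: MlpSpec
) -> np.ndarray:
    """Held-out continuous MLP outputs under leave-one-out cross-validation.

    Features are standardised with training-fold statistics only; the run is
    deterministic given ``spec.seed`` (L-BFGS training with a fixed
    initialisation seed).
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("feature rows must match labels")
    if features.shape[1] < 1:
        raise ValueError("need at least one feature")
    classes = np.unique(labels)
    if classes.size != 2 or np.min(np.bincount(labels.astype(int))) < 2:
        raise ValueError("need two classes with at least 2 subjects each")
    n = features.shape[0]
    scores = np.empty(n)
    y = labels.astype(float)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if np.unique(labels[tr]).size < 2:
            raise ValueError(f"training fold {i} contains a single class")
        Xtr, Xte = features[tr], features[i : i + 1]
        if spec.standardize:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        net = MLPRegressor(
            hidden_layer_sizes=(spec.hidden_units,),
            activation="logistic",
            solver="lbfgs",
            max_iter=spec.max_epochs,
            random_state=spec.seed,
        )
        with warnings.catch_warnings():
            # max_epochs is a deliberate training cap, not a tolerance target
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            net.fit(Xtr, y[tr])
        scores[i] = float(net.predict(Xte)[0])
    return scores


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and Mann–Whitney AUC (ties counted one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    auc = (float(np.sum(ranks[labels == 1])) - n_pos * (n_pos + 1) / 2.0) / (
        n_pos * n_neg
    )
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    if fpr[0] != 0 or tpr[0] != 0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    if fpr[-1] != 1 or tpr[-1] != 1:
        fpr = np.concatenate([fpr, [1.0]])
        tpr = np.concatenate([tpr, [1.0]])
    return RocCurve(fpr=fpr, tpr=tpr, auc=float(auc))
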