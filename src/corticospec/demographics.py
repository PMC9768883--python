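"""Group demographic comparisons: chi-square homogeneity and summary-based ANOVA."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "chisq_homogeneity",
    "anova_from_summary",
    "chisq_report",
    "anova_report",
    "sex_contingency",
    "age_summaries",
]


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean and standard deviation (e.g. age in years)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")


def chisq_homogeneity(table) -> tuple[float, int, float]:
    """Pearson chi-square test of homogeneity, no continuity correction.

    ``table`` is a groups x categories array of non-negative integer counts
    with positive margins.  Returns (statistic, df, p).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def anova_from_summary(
    groups: Sequence[GroupSummary | tuple[int, float, float]],
) -> tuple[float, int, int, float]:
    """One-way ANOVA recomputed from per-group (n, mean, sd) summaries.

    Between-group sum of squares uses the weighted grand mean; the within
    sum of squares is sum (n_i - 1) sd_i^2.  Returns (F, df1, df2, p).
    Agrees exactly with a raw-data ANOVA whenever raw data realise the
    summaries.
    """
    gs = [g if isinstance(g, GroupSummary) else GroupSummary(*g) for g in groups]
    if len(gs) < 2:
        raise ValueError("at least two groups are required")
    ns = np.array([g.n for g in gs], dtype=float)
    means = np.array([g.mean for g in gs])
    sds = np.array([g.sd for g in gs])
    N = ns.sum()
    grand = float(np.sum(ns * means) / N)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    df1 = len(gs) - 1
    df2 = int(N) - len(gs)
    F = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def sex_contingency(cohort: pd.DataFrame) -> np.ndarray:
    """Groups x (M, F) count table from a cohort table (group order HC/LTLE/RTLE)."""
    order = [g for g in ("HC", "LTLE", "RTLE") if g in set(cohort["group"])]
    return np.array(
        [
            [
                int(((cohort["group"] == g) & (cohort["sex"] == s)).sum())
                for s in ("M", "F")
            ]
            for g in order
        ]
    )


def age_summaries(cohort: pd.DataFrame) -> list[GroupSummary]:
    """Per-group age (n, mean, sd) summaries (group order HC/LTLE/RTLE)."""
    order = [g for g in ("HC", "LTLE", "RTLE") if g in set(cohort["group"])]
    out = []
    for g in order:
        ages = cohort.loc[cohort["group"] == g, "age"]
        out.append(GroupSummary(n=len(ages), mean=float(ages.mean()), sd=float(ages.std(ddof=1))))
    return out


def chisq_report(table) -> str:
    stat, df, p = chisq_homogeneity(table)
    return f"chi-square homogeneity: statistic={stat:.2f}, df={df}, p={p:.3f}"


def anova_report(groups) -> str:
    F, df1, df2, p = anova_from_summary(groups)
    return f"one-way ANOVA: F={F:.2f}, df=({df1}, {df2}), p={p:.3f}"
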