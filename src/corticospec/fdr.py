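"""One-sided Bayesian false-discovery-rate maps from posterior samples.

For each region the null hypothesis is "no thinning", H0: B_k(v) >= 0,
against H1: B_k(v) < 0.  The posterior null probability is the fraction of
retained draws with B_k(v) >= 0; regions are sorted by that probability and
the largest prefix whose running mean stays at or below the target rate q is
rejected, which controls the Bayesian FDR (the posterior expected proportion
of true nulls among the rejections) at q.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["FdrResult", "posterior_null_prob", "null_probabilities", "bayesian_fdr_threshold"]

MIN_DRAWS = 100


@dataclasses.dataclass(frozen=True)
class FdrResult:
    """Rejection map at target Bayesian FDR ``q``.

    null_prob : per-region posterior probability of the null B_k(v) >= 0.
    rejected : per-region boolean rejection indicator.
    z_threshold : max posterior z-score among rejected regions (the
        printed-style data-dependent threshold); NaN when nothing is
        rejected or no z-scores were supplied.
    q : the target rate.
    """

    null_prob: np.ndarray
    rejected: np.ndarray
    z_threshold: float
    q: float

    @property
    def n_rejected(self) -> int:
        return int(np.sum(self.rejected))


def posterior_null_prob(draws: np.ndarray) -> float:
    """Fraction of retained draws with the coefficient >= 0 (needs >= 100 draws)."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 1:
        raise ValueError("draws must be one-dimensional")
    if draws.size < MIN_DRAWS:
        raise ValueError(f"need at least {MIN_DRAWS} retained draws, got {draws.size}")
    return float(np.mean(draws >= 0.0))


def null_probabilities(spatial_draws: np.ndarray) -> np.ndarray:
    """Per-region null probabilities from a (draws, regions) array."""
    spatial_draws = np.asarray(spatial_draws, dtype=float)
    if spatial_draws.ndim != 2:
        raise ValueError("expected a (draws, regions) array")
    if spatial_draws.shape[0] < MIN_DRAWS:
        raise ValueError(
            f"need at least {MIN_DRAWS} retained draws, got {spatial_draws.shape[0]}"
        )
    return np.mean(spatial_draws >= 0.0, axis=0)


def bayesian_fdr_threshold(
    null_probs: np.ndarray, q: float, zscores: np.ndarray | None = None
) -> FdrResult:
    """Reject the largest prefix of sorted null probabilities with running mean <= q.

    Ties at the cut are included only while the running mean stays at or
    below ``q`` (guaranteed by the prefix rule on the stably sorted array).
    """
    probs = np.asarray(null_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("null probability vector is empty")
    if np.any(probs < 0) or np.any(probs > 1) or not np.all(np.isfinite(probs)):
        raise ValueError("null probabilities must lie in [0, 1]")
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    order = np.argsort(probs, kind="stable")
    running = np.cumsum(probs[order]) / np.arange(1, probs.size + 1)
    below = np.nonzero(running <= q)[0]
    k = int(below[-1]) + 1 if below.size else 0
    rejected = np.zeros(probs.size, dtype=bool)
    rejected[order[:k]] = True
    if zscores is not None and k > 0:
        z = np.asarray(zscores, dtype=float)
        if z.shape != probs.shape:
            raise ValueError("z-scores must align with the null probabilities")
        z_threshold = float(np.max(z[rejected]))
    else:
        z_threshold = float("nan")
    return FdrResult(null_prob=probs, rejected=rejected, z_threshold=z_threshold, q=float(q))
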