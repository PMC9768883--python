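"""Matérn residual covariance on the sphere and its spectral analogue.

The small-scale residual process is a mean-zero Gaussian process with
nugget-plus-Matérn covariance

    Cov[E(v), E(v')] = sigma^2 1(v = v') + tau^2 M_nu(3 d / phi),

where ``d`` is the chordal distance between unit vectors (chordal rather
than great-circle because the Matérn family is positive definite on chordal
distance for every smoothness) and

    M_nu(u) = 2^(1-nu) / Gamma(nu) * u^nu * K_nu(u),

with ``K_nu`` the modified Bessel function of the second kind.  The factor
3/phi makes phi a range-like parameter: at distance d = phi the correlation
is about 0.05 for nu = 1/2.

In the spectral domain the same four parameters drive the per-degree
coefficient variance

    lambda(l) = sigma^2 + tau^2 * c * (alpha^2 + l(l+1))^(-(nu+1)),

the Matérn/SPDE correspondence on the 2-sphere with alpha = 3/phi and the
constant ``c`` chosen so the discrete spectrum sums to tau^2 (normalisation
over degrees 0..NORMALIZATION_DEGREE).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.special import expit, gamma as gamma_fn, kv, logit

from .harmonics import SphericalPoint

__all__ = [
    "MaternParams",
    "ReparamMatern",
    "matern_correlation",
    "covariance_matrix",
    "spectral_density",
    "spectral_shape",
    "reparam",
    "inverse_reparam",
]

#: degree at which the discrete spectral normalisation sum is truncated.
NORMALIZATION_DEGREE = 50

#: |logit| clamp used when the spatial variance proportion hits 0 or 1.
LOGIT_CLAMP = 30.0


@dataclasses.dataclass(frozen=True)
class MaternParams:
    """Nugget + Matérn parameters theta = (sigma^2, tau^2, phi, nu).

    sigma2 : nugget variance (mm^2), >= 0
    tau2 : spatially structured variance (mm^2), >= 0
    range_ : range phi (> 0), unit-sphere chordal-distance units
    smoothness : Matérn smoothness nu (> 0)
    """

    sigma2: float
    tau2: float
    range_: float
    smoothness: float

    def __post_init__(self) -> None:
        vals = (self.sigma2, self.tau2, self.range_, self.smoothness)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("Matérn parameters must be finite")
        if self.sigma2 < 0 or self.tau2 < 0:
            raise ValueError("variances must be non-negative")
        if self.range_ <= 0 or self.smoothness <= 0:
            raise ValueError("range and smoothness must be positive")

    @property
    def total_variance(self) -> float:
        return self.sigma2 + self.tau2


@dataclasses.dataclass(frozen=True)
class ReparamMatern:
    """Unconstrained re-parameterisation used for MCMC sampling.

    total_variance : v = sigma^2 + tau^2 (> 0)
    spatial_logit : r = logit(tau^2 / v)
    log_range : phi' = log(phi)
    log_smoothness : nu' = log(nu)
    """

    total_variance: float
    spatial_logit: float
    log_range: float
    log_smoothness: float

    def __post_init__(self) -> None:
        if not self.total_variance > 0:
            raise ValueError("total variance must be positive")


def matern_correlation(d, range_: float, smoothness: float):
    """Matérn correlation M(d) = 2^(1-nu)/Gamma(nu) (3d/phi)^nu K_nu(3d/phi).

    Accepts scalar or array distances ``d >= 0``; M(0) = 1 by the limit.
    """
    if range_ <= 0 or smoothness <= 0:
        raise ValueError("range and smoothness must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    u = 3.0 * d / range_
    nu = smoothness
    with np.errstate(invalid="ignore", over="ignore"):
        corr = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * u**nu * kv(nu, u)
    # kv underflows to 0 and u**nu to inf at the extremes; both limits are 0,
    # while u -> 0 gives correlation 1.
    corr = np.where(u == 0.0, 1.0, np.nan_to_num(corr, nan=0.0, posinf=0.0))
    corr = np.clip(corr, 0.0, 1.0)
    return float(corr) if corr.ndim == 0 else corr


def _chordal_distances(points: Sequence[SphericalPoint]) -> np.ndarray:
    vecs = np.array([p.unit_vector() for p in points])
    gram = np.clip(vecs @ vecs.T, -1.0, 1.0)
    sq = np.maximum(2.0 - 2.0 * gram, 0.0)
    return np.sqrt(sq)


def covariance_matrix(points: Sequence[SphericalPoint], params: MaternParams) -> np.ndarray:
    """Nugget + Matérn covariance at a point set (chordal distances).

    Entry (i, j) is sigma^2 1(i = j) + tau^2 M(d_ij); the diagonal equals
    sigma^2 + tau^2.  Duplicate points get tau^2 off-diagonal (distance 0).
    """
    if len(points) == 0:
        raise ValueError("at least one point is required")
    d = _chordal_distances(points)
    if params.tau2 == 0.0:
        cov = np.zeros_like(d)
    else:
        cov = params.tau2 * matern_correlation(d, params.range_, params.smoothness)
    cov[np.diag_indices_from(cov)] = params.total_variance
    return cov


def spectral_shape(l, spatial_proportion: float, range_: float, smoothness: float):
    """Unit-total-variance spectral profile g(l) with lambda(l) = v * g(l).

    g(l) = (1-p) + p * c * (alpha^2 + l(l+1))^(-(nu+1)) where p is the
    spatial variance proportion, alpha = 3/phi, and c normalises the
    discrete spectrum: sum_{l=0..50} (2l+1) c (alpha^2+l(l+1))^(-(nu+1)) = 1.
    """
    l = np.asarray(l, dtype=float)
    alpha2 = (3.0 / range_) ** 2
    expo = -(smoothness + 1.0)
    ln = np.arange(NORMALIZATION_DEGREE + 1, dtype=float)
    norm = np.sum((2 * ln + 1) * (alpha2 + ln * (ln + 1)) ** expo)
    c = 1.0 / norm
    f = (alpha2 + l * (l + 1.0)) ** expo
    g = (1.0 - spatial_proportion) + spatial_proportion * c * f
    return float(g) if g.ndim == 0 else g


def spectral_density(l, params: MaternParams):
    """Per-degree coefficient variance lambda(l) = sigma^2 + tau^2 c (alpha^2 + l(l+1))^(-(nu+1)).

    Depends on the degree only (isotropy); with tau^2 = 0 it is the flat
    nugget sigma^2, and with sigma^2 = 0 the discrete spectrum
    sum (2l+1) lambda(l) over degrees 0..50 equals tau^2.
    """
    if int(np.min(np.asarray(l))) < 0:
        raise ValueError("degree l must be >= 0")
    v = params.total_variance
    if v == 0.0:
        out = np.zeros_like(np.asarray(l, dtype=float))
        return float(out) if out.ndim == 0 else out
    p = params.tau2 / v
    return v * spectral_shape(l, p, params.range_, params.smoothness)


def reparam(params: MaternParams) -> ReparamMatern:
    """Map theta to the unconstrained (v, r, log phi, log nu) block.

    A zero nugget or zero spatial variance pushes the logit to +/-inf; it is
    clamped to +/-30 with a warning (expit(30) is 1 to double precision).
    """
    v = params.total_variance
    if v <= 0:
        raise ValueError("reparameterisation requires sigma^2 + tau^2 > 0")
    prop = params.tau2 / v
    if prop in (0.0, 1.0):
        warnings.warn(
            "spatial proportion at boundary; clamping logit to +/-30",
            RuntimeWarning,
            stacklevel=2,
        )
        r = LOGIT_CLAMP if prop == 1.0 else -LOGIT_CLAMP
    else:
        r = float(logit(prop))
    return ReparamMatern(
        total_variance=v,
        spatial_logit=r,
        log_range=float(np.log(params.range_)),
        log_smoothness=float(np.log(params.smoothness)),
    )


def inverse_reparam(rp: ReparamMatern) -> MaternParams:
    """Inverse of :func:`reparam` (exact bijection away from the clamp)."""
    prop = float(expit(rp.spatial_logit))
    return MaternParams(
        sigma2=rp.total_variance * (1.0 - prop),
        tau2=rp.total_variance * prop,
        range_=float(np.exp(rp.log_range)),
        smoothness=float(np.exp(rp.log_smoothness)),
    )
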