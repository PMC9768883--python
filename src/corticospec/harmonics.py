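"""Real spherical-harmonic bases at scattered points on the unit sphere.

Region-averaged cortical measurements live at one centroid per atlas region,
scattered irregularly over the sphere.  A field sampled there is expanded in
real spherical harmonics by least squares (ridge-regularised when the
evaluation matrix is ill-conditioned); the expansion approximately
de-correlates stationary Gaussian processes on the sphere, so a dense
spatial covariance becomes a set of independent per-coefficient variances.

Conventions
-----------
* The unnormalised complex harmonic is ``S_l^m(s1, s2) = P_l^m(cos s1)
  e^{-i m s2}`` with colatitude ``s1`` and longitude ``s2``; ``P_l^m``
  carries the Condon–Shortley phase (as in :func:`scipy.special.lpmv`).
* The real basis has exactly ``(L+1)**2`` columns, ordered by increasing
  degree ``l``, then increasing order ``m``; for ``m > 0`` the real part
  precedes the imaginary part and both are scaled by ``sqrt(2)`` so the
  real representation is an isometry of the conjugate-symmetric complex one.
* Basis columns use Schmidt semi-normalised Legendre functions — the m > 0
  columns carry the factor ``sqrt((l-m)!/(l+m)!)`` — so every column of a
  given degree has the same L2 norm on the sphere (the unnormalised
  ``P_l^m`` spread over ~9 orders of magnitude by l = m = 7, which would
  destroy both the conditioning of the transform and the premise that
  coefficient variances depend on the degree only).
* Every column additionally carries the ``1/sqrt(2l+1)`` factor of the
  truncated expansion, so coefficient vectors are directly comparable across
  degrees; the (0, 0) column is identically 1.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln, lpmv

__all__ = [
    "SphericalPoint",
    "HarmonicIndex",
    "HarmonicBasis",
    "assoc_legendre",
    "spherical_harmonic",
    "build_basis",
    "forward_sht",
    "inverse_sht",
    "frequency_set",
]

_TWO_PI = 2.0 * np.pi

#: condition-number threshold above which the least-squares transform
#: switches to the ridge-regularised solve.
ILL_CONDITION_THRESHOLD = 1e10

#: relative ridge used for rank-deficient / ill-conditioned evaluation
#: matrices: ridge = RIDGE_FACTOR * trace(A'A) / n_columns.
RIDGE_FACTOR = 1e-8


@dataclasses.dataclass(frozen=True)
class SphericalPoint:
    """A location on the unit sphere: colatitude in [0, pi], longitude wrapped to [0, 2*pi)."""

    colatitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.colatitude) and np.isfinite(self.longitude)):
            raise ValueError("spherical coordinates must be finite")
        if not 0.0 <= self.colatitude <= np.pi:
            raise ValueError(f"colatitude {self.colatitude} outside [0, pi]")
        object.__setattr__(self, "longitude", float(self.longitude) % _TWO_PI)
        object.__setattr__(self, "colatitude", float(self.colatitude))

    def unit_vector(self) -> np.ndarray:
        """Cartesian unit vector (x, y, z) for this point."""
        s1, s2 = self.colatitude, self.longitude
        return np.array(
            [np.sin(s1) * np.cos(s2), np.sin(s1) * np.sin(s2), np.cos(s1)]
        )


class HarmonicIndex(NamedTuple):
    """Spherical-harmonic frequency omega = (degree l, order m)."""

    degree: int
    order: int


def _validate_index(l: int, m: int) -> None:
    if int(l) != l or int(m) != m:
        raise ValueError("degree and order must be integers")
    if l < 0:
        raise ValueError(f"degree l={l} must be >= 0")
    if abs(m) > l:
        raise ValueError(f"|m|={abs(m)} exceeds degree l={l}")


def assoc_legendre(l: int, m: int, x: float) -> float:
    """Associated Legendre function P_l^m(x), Condon–Shortley phase included.

    Parameters
    ----------
    l, m : int
        Degree and order with ``|m| <= l``.
    x : float
        Argument in [-1, 1] (the cosine of a colatitude).
    """
    _validate_index(l, m)
    if abs(x) > 1.0:
        raise ValueError(f"argument x={x} outside [-1, 1]")
    return float(lpmv(m, l, x))


def spherical_harmonic(index: HarmonicIndex | tuple[int, int], point: SphericalPoint) -> complex:
    """Unnormalised complex harmonic S_l^m = P_l^m(cos s1) * exp(-i m s2)."""
    l, m = index
    _validate_index(l, m)
    p = assoc_legendre(l, m, float(np.cos(point.colatitude)))
    return complex(p * np.exp(-1j * m * point.longitude))


@dataclasses.dataclass(frozen=True)
class HarmonicBasis:
    """Real spherical-harmonic design matrix at a fixed set of points.

    Attributes
    ----------
    max_degree : int
        Truncation degree L; the basis spans all degrees 0..L.
    columns : tuple of (l, m, part)
        Deterministic column ordering: degree ascending, order ascending,
        real part before imaginary part ("re" for m = 0).
    matrix : ndarray, shape (n_points, (L+1)**2)
        Evaluation matrix; column (l, m, part) is the scaled real/imaginary
        part of S_l^m at every point.
    points : tuple of SphericalPoint
    """

    max_degree: int
    columns: tuple[tuple[int, int, str], ...]
    matrix: np.ndarray
    points: tuple[SphericalPoint, ...]

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def degrees(self) -> np.ndarray:
        """Degree l of each real column, shape (n_columns,)."""
        return np.array([c[0] for c in self.columns])

    def column_labels(self) -> list[str]:
        return [f"l{l}_m{m}_{part}" for l, m, part in self.columns]


def build_basis(points: Sequence[SphericalPoint], L: int) -> HarmonicBasis:
    """Evaluate the real harmonic basis up to degree ``L`` at scattered points.

    For each degree l the m = 0 harmonic contributes one real column and each
    m in 1..l contributes a sqrt(2)-scaled real and imaginary column, for
    ``(L+1)**2`` columns total.  Columns are Schmidt semi-normalised
    (factor sqrt((l-m)!/(l+m)!) for m > 0) and carry the 1/sqrt(2l+1)
    factor of the truncated expansion.
    """
    if len(points) == 0:
        raise ValueError("at least one evaluation point is required")
    if int(L) != L or L < 0:
        raise ValueError(f"max degree L={L} must be a non-negative integer")
    s1 = np.array([p.colatitude for p in points])
    s2 = np.array([p.longitude for p in points])
    cos_s1 = np.cos(s1)

    cols: list[np.ndarray] = []
    index: list[tuple[int, int, str]] = []
    for l in range(int(L) + 1):
        scale = 1.0 / np.sqrt(2 * l + 1)
        p0 = lpmv(0, l, cos_s1)
        cols.append(scale * p0)
        index.append((l, 0, "re"))
        for m in range(1, l + 1):
            schmidt = np.sqrt(
                np.exp(gammaln(l - m + 1) - gammaln(l + m + 1))
            )
            plm = schmidt * lpmv(m, l, cos_s1)
            # S_l^m = P_l^m(cos s1) e^{-i m s2}: Re = P cos(m s2), Im = -P sin(m s2)
            cols.append(scale * np.sqrt(2.0) * plm * np.cos(m * s2))
            index.append((l, m, "re"))
            cols.append(scale * np.sqrt(2.0) * (-plm * np.sin(m * s2)))
            index.append((l, m, "im"))
    matrix = np.column_stack(cols)
    return HarmonicBasis(
        max_degree=int(L),
        columns=tuple(index),
        matrix=matrix,
        points=tuple(points),
    )


def forward_sht(values: np.ndarray, basis: HarmonicBasis) -> np.ndarray:
    """Least-squares coefficients of a field sampled at the basis points.

    Uses a plain least-squares solve when the evaluation matrix is
    well-conditioned, and a ridge-regularised normal-equation solve
    (ridge = 1e-8 * trace(A'A)/n_columns) when it is rank deficient or its
    condition number exceeds ``ILL_CONDITION_THRESHOLD``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (basis.n_points,):
        raise ValueError(
            f"value count {values.shape} does not match point count {basis.n_points}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("field values must be finite")
    A = basis.matrix
    singular = np.linalg.svd(A, compute_uv=False)
    well_posed = (
        A.shape[0] >= A.shape[1]
        and singular[-1] > 0
        and singular[0] / singular[-1] < ILL_CONDITION_THRESHOLD
    )
    if well_posed:
        coeffs, *_ = np.linalg.lstsq(A, values, rcond=None)
        return coeffs
    gram = A.T @ A
    ridge = RIDGE_FACTOR * np.trace(gram) / A.shape[1]
    coeffs = np.linalg.solve(gram + ridge * np.eye(A.shape[1]), A.T @ values)
    return coeffs


def inverse_sht(coeffs: np.ndarray, basis: HarmonicBasis) -> np.ndarray:
    """Synthesise the field at the basis points from real coefficients."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (basis.n_columns,):
        raise ValueError(
            f"coefficient length {coeffs.shape} does not match basis columns {basis.n_columns}"
        )
    return basis.matrix @ coeffs


def frequency_set(J: int, basis: HarmonicBasis) -> tuple[int, ...]:
    """Indices of the ``J`` lowest-frequency real columns (the set L of retained terms)."""
    if int(J) != J or not 1 <= J <= basis.n_columns:
        raise ValueError(f"J={J} outside [1, {basis.n_columns}]")
    return tuple(range(int(J)))
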