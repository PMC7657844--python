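"""Pairwise matrices consumed by the embedding optimizer.

This module builds, from a high-dimensional sample matrix ``Y``:

* squared Euclidean distances ``D`` (which double as the raw repulsive
  weights),
* attractive weights ``exp(-D[n, m] / (2 * sigma_n**2))`` with per-sample
  bandwidths ``sigma_n`` calibrated so each sample's conditional neighbor
  distribution hits a common perplexity (``2**H``, entropy in bits),
* normalized repulsive weights, and
* optional normalized temporal dissimilarities for time-series embedding.

Attractive and repulsive matrices are symmetrized (attractive only; the
distance matrix is already symmetric), zero-diagonal, and normalized to total
sum 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import (
    DegenerateAffinityError,
    DuplicateRowError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "DataMatrix",
    "AffinityModel",
    "pairwise_sq_dist",
    "calibrate_sigma",
    "calibrate_all_sigmas",
    "sigma_order",
    "build_attractive",
    "symmetrize_normalize",
    "normalize_repulsive",
    "build_temporal",
    "build_affinities",
]

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)

# Bisection stops when the achieved perplexity is this close (relative) to the
# target.  The contract only requires 1e-6; converging tighter makes the
# result insensitive to the processing order and to warm starts, which keeps
# the serial and row-partitioned parallel paths numerically consistent.
_PERP_RTOL = 1e-10
_MAX_BISECT = 200
_MAX_EXPAND = 90


@dataclass(frozen=True)
class DataMatrix:
    """N samples by D features, all entries finite, N >= 2."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise InvalidInputError(f"expected a 2-D matrix, got ndim={v.ndim}")
        if v.shape[0] < 2:
            raise InvalidInputError("need at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise InvalidInputError("data matrix contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def as_values(Y) -> np.ndarray:
    """Coerce a DataMatrix or array-like into a validated float64 array."""
    if isinstance(Y, DataMatrix):
        return Y.values
    return DataMatrix(np.asarray(Y)).values


@dataclass
class AffinityModel:
    """Normalized pairwise weights feeding the energy function.

    ``w_p`` and ``w_n`` are symmetric, zero-diagonal and sum to one;
    ``temporal`` (optional) follows the same convention.  ``sigma`` holds the
    calibrated per-sample bandwidths.
    """

    w_p: np.ndarray
    w_n: np.ndarray
    sigma: np.ndarray
    perplexity: float
    temporal: np.ndarray | None = field(default=None)

    @property
    def n_samples(self) -> int:
        return self.w_p.shape[0]

    def validate(self, atol: float = 1e-12) -> None:
        n = self.n_samples
        for name, m in (("w_p", self.w_p), ("w_n", self.w_n)):
            if m.shape != (n, n):
                raise InvalidInputError(f"{name} must be {n}x{n}")
            if not np.array_equal(m, m.T):
                if not np.allclose(m, m.T, atol=atol):
                    raise InvalidInputError(f"{name} is not symmetric")
            if np.any(np.diagonal(m) != 0.0):
                raise InvalidInputError(f"{name} has nonzero diagonal")
            if np.any(m < 0.0):
                raise InvalidInputError(f"{name} has negative entries")
            if abs(m.sum() - 1.0) > atol:
                raise InvalidInputError(f"{name} does not sum to 1")
        if not 1.0 < self.perplexity <= n - 1:
            raise InvalidParameterError(
                f"perplexity {self.perplexity} outside (1, {n - 1}]"
            )
        if self.temporal is not None:
            t = self.temporal
            total = t.sum()
            if t.shape != (n, n) or np.any(np.diagonal(t) != 0.0):
                raise InvalidInputError("temporal matrix malformed")
            if total != 0.0 and abs(total - 1.0) > atol:
                raise InvalidInputError("temporal matrix does not sum to 1")


def sq_dist_rows(Y_rows: np.ndarray, Y: np.ndarray, row_offset: int = 0) -> np.ndarray:
    """Squared Euclidean distances between ``Y_rows`` and all rows of ``Y``.

    ``Y_rows`` must be ``Y[row_offset:row_offset + m]``; the self-distance of
    each row is forced to exactly zero.  Row-independent, so a block of rows
    computed here is bitwise identical to the same rows of the full matrix.
    """
    D = cdist(Y_rows, Y, "sqeuclidean")
    np.maximum(D, 0.0, out=D)
    m = Y_rows.shape[0]
    D[np.arange(m), np.arange(row_offset, row_offset + m)] = 0.0
    return D


def pairwise_sq_dist(Y) -> np.ndarray:
    """Full symmetric matrix of squared Euclidean distances.

    The result is exactly symmetric with a zero diagonal; round-off negatives
    are clamped to zero.
    """
    v = as_values(Y)
    return sq_dist_rows(v, v, 0)


def _perplexity_of(d: np.ndarray, sigma: float) -> float:
    """Achieved perplexity 2**H (entropy in bits) of p_m ~ exp(-d_m/(2 s^2)).

    Computed in shifted form so it is stable for very small sigma.
    """
    beta = 1.0 / (2.0 * sigma * sigma)
    shifted = d - d.min()
    e = np.exp(-beta * shifted)
    s = e.sum()
    # H (nats) = ln s + beta * <shifted>_p ; perplexity = exp(H)
    h_nats = np.log(s) + beta * float(e @ shifted) / s
    return float(np.exp(h_nats))


def conditional_distribution(
    D_row: np.ndarray, self_index: int, sigma: float
) -> np.ndarray:
    """Length-N conditional neighbor distribution for one sample (self prob 0)."""
    d = np.asarray(D_row, dtype=np.float64)
    n = d.size
    mask = np.ones(n, dtype=bool)
    mask[self_index] = False
    off = d[mask]
    p = np.zeros(n)
    if np.all(off == 0.0):
        p[mask] = 1.0 / (n - 1)
        return p
    beta = 1.0 / (2.0 * sigma * sigma)
    e = np.exp(-beta * (off - off.min()))
    p[mask] = e / e.sum()
    return p


def calibrate_sigma(
    D_row: np.ndarray,
    self_index: int,
    perplexity: float,
    init: float | None = None,
) -> float:
    """Find sigma so the conditional distribution over neighbors has the
    target perplexity.

    Root-finding is bisection on log(sigma).  The bracket is first located by
    geometric expansion from ``init`` (the previous sample's solution when
    processed in a warm-start chain) and then snapped to the canonical dyadic
    interval [2**(b-1), 2**b] where b is the smallest integer exponent with
    achieved perplexity >= target.  The bisection path is therefore a pure
    function of the distance row: warm starts change only how fast the
    bracket is found, never the returned sigma.  Achieved perplexity matches
    the target to better than 1e-6 relative (1e-10 in practice).
    """
    d = np.asarray(D_row, dtype=np.float64)
    n = d.size
    if not 1.0 < perplexity <= n - 1:
        raise InvalidParameterError(
            f"perplexity must lie in (1, N-1] = (1, {n - 1}], got {perplexity}"
        )
    mask = np.ones(n, dtype=bool)
    mask[self_index] = False
    off = d[mask]
    if np.any(off < 0) or not np.all(np.isfinite(off)):
        raise InvalidInputError("distances must be finite and nonnegative")
    if np.all(off == 0.0):
        raise DuplicateRowError(
            f"all off-self distances of row {self_index} are zero"
        )

    target = float(perplexity)
    tol = _PERP_RTOL * target
    sigma0 = float(init) if init is not None else 1.0

    # Flat distribution (equidistant neighbors): any sigma achieves the
    # target, so keep the caller's initial value.
    f0 = _perplexity_of(off, sigma0)
    if abs(f0 - target) <= tol and abs(_perplexity_of(off, 2.0 * sigma0) - target) <= tol:
        return sigma0

    # Canonical dyadic bracket: smallest integer b with f(2**b) >= target.
    # Start the exponent walk at the warm-start value (speed only).
    b = int(np.clip(round(np.log2(sigma0)), -_MAX_EXPAND, _MAX_EXPAND))
    f_b = _perplexity_of(off, 2.0**b)
    if f_b >= target:
        while b > -_MAX_EXPAND:
            f_dn = _perplexity_of(off, 2.0 ** (b - 1))
            if f_dn < target:
                break
            b -= 1
            f_b = f_dn
        else:
            return 2.0**b  # unattainable below (tied nearest neighbors)
    else:
        while b < _MAX_EXPAND:
            b += 1
            f_b = _perplexity_of(off, 2.0**b)
            if f_b >= target:
                break
        else:
            return 2.0**b  # target at/above the attainable supremum

    # Bisection on log2(sigma) over [b-1, b]; dyadic midpoints make every
    # iterate exactly reproducible.
    lo, hi = float(b - 1), float(b)
    best, best_err = 2.0**b, abs(f_b - target)
    for _ in range(_MAX_BISECT):
        mid = 0.5 * (lo + hi)
        sigma = float(2.0**mid)
        f_mid = _perplexity_of(off, sigma)
        err = abs(f_mid - target)
        if err < best_err:
            best, best_err = sigma, err
        if err <= tol:
            return sigma
        if f_mid < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14:
            break
    if best_err > 1e-6 * target:
        logger.warning(
            "sigma calibration stalled: achieved perplexity off target by %.3g",
            best_err / target,
        )
    return best


def sigma_order(D_sub: np.ndarray, start: int = 0) -> np.ndarray:
    """Greedy nearest-neighbor processing order over the rows of ``D_sub``.

    Starting from ``start``, each next row is the unvisited row closest to the
    current one.  Consecutive rows are therefore near neighbors, which makes
    warm-started bandwidth calibration converge in few iterations.
    """
    D_sub = np.asarray(D_sub)
    n = D_sub.shape[0]
    order = np.empty(n, dtype=np.intp)
    visited = np.zeros(n, dtype=bool)
    current = start
    order[0] = current
    visited[current] = True
    row = D_sub[current].copy()
    for k in range(1, n):
        row[visited] = np.inf
        current = int(np.argmin(row))
        order[k] = current
        visited[current] = True
        row = D_sub[current].copy()
    return order


def calibrate_all_sigmas(
    D: np.ndarray,
    perplexity: float,
    order: np.ndarray | None = None,
) -> np.ndarray:
    """Calibrate every sample's bandwidth, warm-starting along ``order``.

    Each root-finding problem is seeded with the previous solution (the first
    with 1.0).  Results are order-invariant; only speed depends on the order.
    Duplicate rows (all off-self distances zero) get sigma equal to the
    smallest positive normal float, with a warning.
    """
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    if order is None:
        order = sigma_order(D)
    order = np.asarray(order, dtype=np.intp)
    if sorted(order.tolist()) != list(range(n)):
        raise InvalidParameterError("order must be a permutation of all rows")
    sigma = np.empty(n)
    init = 1.0
    for idx in order:
        try:
            s = calibrate_sigma(D[idx], int(idx), perplexity, init=init)
        except DuplicateRowError:
            warnings.warn(
                f"row {idx} duplicates another sample; using uniform "
                "conditional distribution",
                RuntimeWarning,
                stacklevel=2,
            )
            sigma[idx] = np.finfo(np.float64).tiny
            continue
        sigma[idx] = s
        init = s
    return sigma


def build_attractive(D: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Raw attractive weights exp(-D[n, m] / (2 sigma_n^2)), zero diagonal.

    Row-asymmetric in general because the bandwidth is row-specific.
    """
    D = np.asarray(D, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise InvalidParameterError("sigma must be positive")
    inv = 1.0 / (2.0 * sigma * sigma)
    W = np.exp(-D * inv[:, None])
    np.fill_diagonal(W, 0.0)
    return W


def symmetrize_normalize(W_raw: np.ndarray) -> np.ndarray:
    """Symmetrize by W + W.T, then divide by the total sum of entries."""
    W_raw = np.asarray(W_raw, dtype=np.float64)
    if np.any(np.diagonal(W_raw) != 0.0):
        raise InvalidInputError("raw weight matrix must have zero diagonal")
    S = W_raw + W_raw.T
    # row sums first: the total is then independent of how rows are blocked
    # across workers, which keeps the parallel path exactly consistent
    total = float(np.sum(S.sum(axis=1)))
    if total == 0.0:
        raise DegenerateAffinityError("all attractive weights are zero")
    return S / total


def normalize_repulsive(D: np.ndarray) -> np.ndarray:
    """Normalize the (already symmetric) squared-distance matrix to sum 1."""
    D = np.asarray(D, dtype=np.float64)
    total = float(np.sum(D.sum(axis=1)))
    if total == 0.0:
        raise DegenerateAffinityError(
            "all samples are identical; repulsive weights are degenerate"
        )
    return D / total


def build_temporal(
    t: np.ndarray, n_samples: int | None = None, dialect: str = "squared"
) -> np.ndarray:
    """Normalized pairwise time dissimilarities.

    ``dialect`` is "squared" (default, mirrors the squared-distance repulsive
    weights) or "absolute".  All-equal time stamps yield an all-zero matrix
    with a warning, in which case the time-series energy reduces to plain EE.
    """
    t = np.asarray(t, dtype=np.float64).ravel()
    if not np.all(np.isfinite(t)):
        raise InvalidInputError("time stamps must be finite")
    if n_samples is not None and t.size != n_samples:
        raise InvalidInputError(
            f"expected {n_samples} time stamps, got {t.size}"
        )
    if dialect not in ("squared", "absolute"):
        raise InvalidParameterError(f"unknown temporal dialect {dialect!r}")
    diff = t[:, None] - t[None, :]
    T = diff * diff if dialect == "squared" else np.abs(diff)
    np.fill_diagonal(T, 0.0)
    total = float(np.sum(T))
    if total == 0.0:
        warnings.warn(
            "all time stamps identical; temporal term vanishes and the "
            "time-series energy reduces to the plain one",
            RuntimeWarning,
            stacklevel=2,
        )
        return T
    return T / total


def build_affinities(
    Y,
    perplexity: float = 20.0,
    times: np.ndarray | None = None,
    temporal_dialect: str = "squared",
) -> AffinityModel:
    """Full affinity pipeline: distances -> sigma calibration -> normalized
    attractive/repulsive (and optional temporal) weights."""
    v = as_values(Y)
    D = pairwise_sq_dist(v)
    sigma = calibrate_all_sigmas(D, perplexity)
    w_p = symmetrize_normalize(build_attractive(D, sigma))
    w_n = normalize_repulsive(D)
    temporal = None
    if times is not None:
        temporal = build_temporal(times, v.shape[0], dialect=temporal_dialect)
    return AffinityModel(
        w_p=w_p, w_n=w_n, sigma=sigma, perplexity=float(perplexity),
        temporal=temporal,
    )
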