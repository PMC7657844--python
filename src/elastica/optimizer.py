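"""Energy minimization for elastic embedding.

The energy over low-dimensional coordinates ``X`` is

    E(X) = sum_mn wp_mn ||x_n - x_m||^2
         + lambda * sum_mn (wn_mn [+ beta * t_mn]) * exp(-||x_n - x_m||^2)

with normalized attractive weights ``wp``, repulsive weights ``wn`` and
optional temporal dissimilarities ``t``.  Minimization uses a quasi-Newton
scheme: the search direction solves ``B P = -G`` where ``B`` is the
regularized attractive Laplacian ``4 L_P + mu I`` — fixed across iterations,
so it is factorized once — and ``G = 4 L_k X`` is the gradient built from the
current kernel matrix.  Steps are accepted by Armijo backtracking.

Note on constants: the quadratic/exponential energy above differentiates to
``G = 4 L_k X``; the preconditioner carries the matching factor so the unit
step of an exact Newton method stays meaningful.  The direction is unchanged
up to scale and the line search absorbs the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from ._kernels import block_gradient, block_row_energies
from .affinity import (
    AffinityModel,
    DataMatrix,
    as_values,
    build_affinities,
    sq_dist_rows,
)
from .exceptions import (
    InvalidDirectionError,
    InvalidInputError,
    InvalidParameterError,
    NumericalError,
)

__all__ = [
    "EEParams",
    "Embedding",
    "Preconditioner",
    "IterationWork",
    "energy",
    "laplacian",
    "gradient",
    "build_preconditioner",
    "solve_direction",
    "line_search",
    "fit",
    "relative_error",
]

logger = logging.getLogger(__name__)

_ARMIJO_C = 1e-4
_ARMIJO_RHO = 0.8
_MAX_BACKTRACK = 60


@dataclass(frozen=True)
class EEParams:
    """Hyper-parameters of the embedding optimizer.

    ``lambda_`` trades off the attractive and repulsive terms (default 10),
    ``perplexity`` targets the effective neighbor count of the calibrated
    affinities (default 20), ``beta`` scales the temporal term, ``mu`` is the
    diagonal regularizer of the preconditioner ("auto" scales it to the mean
    degree so conditioning is scale-free).
    """

    lambda_: float = 10.0
    perplexity: float = 20.0
    dim: int = 2
    beta: float = 1.0
    mu: float | str = "auto"
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0
    init_scale: float = 1e-4
    temporal_dialect: str = "squared"

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise InvalidParameterError("lambda_ must be positive")
        if self.dim < 1:
            raise InvalidParameterError("dim must be >= 1")
        if self.beta < 0:
            raise InvalidParameterError("beta must be nonnegative")
        if self.tol <= 0:
            raise InvalidParameterError("tol must be positive")
        if self.max_iter < 1:
            raise InvalidParameterError("max_iter must be >= 1")
        if self.init_scale <= 0:
            raise InvalidParameterError("init_scale must be positive")
        if isinstance(self.mu, str):
            if self.mu != "auto":
                raise InvalidParameterError("mu must be a positive number or 'auto'")
        elif self.mu <= 0:
            raise InvalidParameterError("mu must be a positive number or 'auto'")


@dataclass
class Embedding:
    """Optimization result: coordinates plus the iteration trace."""

    coords: np.ndarray
    energy_trace: np.ndarray
    step_trace: np.ndarray
    n_iter: int
    converged: bool
    reason: str = ""


@dataclass
class Preconditioner:
    """Regularized attractive Laplacian ``B = 4 L_P + mu I`` and its one-time
    triangular (Cholesky) factorization, reused for every solve."""

    matrix: np.ndarray
    factorization: tuple
    mu: float

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return scipy.linalg.cho_solve(self.factorization, rhs)


@dataclass
class IterationWork:
    """Per-iteration intermediates (kernel, reweighted Laplacian, gradient)."""

    kernel: np.ndarray
    w_k: np.ndarray
    l_k: np.ndarray
    gradient: np.ndarray
    direction: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Row-block kernels.  Both the serial path (one block covering all rows) and
# the row-partitioned parallel path call these, so a single-worker parallel
# run is bitwise identical to the serial one.
# ---------------------------------------------------------------------------

def repulsive_combination(model: AffinityModel, beta: float) -> np.ndarray:
    """wn, or wn + beta * t when a temporal term is active."""
    if model.temporal is None or beta == 0.0:
        return model.w_n
    return model.w_n + beta * model.temporal


def eval_rows(
    X_rows: np.ndarray, X: np.ndarray, row_offset: int
) -> tuple[np.ndarray, np.ndarray]:
    """Squared distances and kernel exp(-d^2) for a row block of X."""
    sqd = sq_dist_rows(X_rows, X, row_offset)
    ker = np.exp(-sqd)
    return sqd, ker


def energy_from_parts(
    sqd: np.ndarray,
    ker: np.ndarray,
    wp_rows: np.ndarray,
    rep_rows: np.ndarray,
    lam: float,
) -> float:
    return float(np.sum(wp_rows * sqd)) + lam * float(np.sum(rep_rows * ker))


def energy_rows(
    X_rows: np.ndarray,
    X: np.ndarray,
    wp_rows: np.ndarray,
    rep_rows: np.ndarray,
    lam: float,
    row_offset: int,
) -> float:
    """Energy contribution of a contiguous row block."""
    sqd, ker = eval_rows(X_rows, X, row_offset)
    return energy_from_parts(sqd, ker, wp_rows, rep_rows, lam)


def laplacian_rows(W_rows: np.ndarray, row_offset: int) -> np.ndarray:
    """Rows of diag(rowsum) - W for a row block of a symmetric W."""
    m = W_rows.shape[0]
    rowsums = W_rows.sum(axis=1)
    L = -W_rows
    L[np.arange(m), np.arange(row_offset, row_offset + m)] += rowsums
    return L


def gradient_from_kernel(
    X: np.ndarray,
    ker: np.ndarray,
    wp_rows: np.ndarray,
    rep_rows: np.ndarray,
    lam: float,
    row_offset: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradient rows 4 (L_k X) given a precomputed kernel block."""
    w_k = wp_rows - lam * rep_rows * ker
    l_k = laplacian_rows(w_k, row_offset)
    G = 4.0 * (l_k @ X)
    return G, w_k, l_k


def gradient_rows(
    X: np.ndarray,
    wp_rows: np.ndarray,
    rep_rows: np.ndarray,
    lam: float,
    row_offset: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gradient rows 4 (L_k X) for a block, plus the kernel/w_k/L_k rows."""
    m = wp_rows.shape[0]
    _sqd, ker = eval_rows(X[row_offset : row_offset + m], X, row_offset)
    G, w_k, l_k = gradient_from_kernel(X, ker, wp_rows, rep_rows, lam, row_offset)
    return G, ker, w_k, l_k


def initial_coords(n: int, dim: int, seed: int, init_scale: float) -> np.ndarray:
    """Seeded i.i.d. Gaussian initialization N(0, init_scale^2)."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, dim)) * init_scale


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def _check_coords(X: np.ndarray, model: AffinityModel) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != model.n_samples:
        raise InvalidInputError(
            f"coordinates must be {model.n_samples} x d, got {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("coordinates contain non-finite entries")
    return X


def energy(X: np.ndarray, model: AffinityModel, params: EEParams) -> float:
    """Evaluate the embedding energy at coordinates ``X``."""
    X = _check_coords(X, model)
    rep = repulsive_combination(model, params.beta)
    return energy_rows(X, X, model.w_p, rep, params.lambda_, 0)


def laplacian(W: np.ndarray) -> np.ndarray:
    """Graph Laplacian diag(rowsum) - W of a symmetric zero-diagonal W."""
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidInputError("W must be square")
    if not np.array_equal(W, W.T):
        if not np.allclose(W, W.T, rtol=1e-12, atol=1e-15):
            raise InvalidInputError("W must be symmetric")
    return laplacian_rows(W, 0)


def gradient(
    X: np.ndarray, model: AffinityModel, params: EEParams
) -> tuple[np.ndarray, IterationWork]:
    """Analytic gradient 4 L_k X of the energy, with the iteration workspace."""
    X = _check_coords(X, model)
    rep = repulsive_combination(model, params.beta)
    G, ker, w_k, l_k = gradient_rows(X, model.w_p, rep, params.lambda_, 0)
    return G, IterationWork(kernel=ker, w_k=w_k, l_k=l_k, gradient=G)


def resolve_mu(B_unregularized_trace: float, n: int, mu: float | str) -> float:
    if isinstance(mu, str):
        return 1e-9 * B_unregularized_trace / n
    return float(mu)


def factorize_spd(B: np.ndarray) -> tuple:
    try:
        return scipy.linalg.cho_factor(B, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(
            "preconditioner factorization failed; try a larger mu"
        ) from exc


def build_preconditioner(model: AffinityModel, params: EEParams) -> Preconditioner:
    """Assemble and factorize ``B = 4 L_P + mu I`` (done once per fit)."""
    B = 4.0 * laplacian_rows(model.w_p, 0)
    n = B.shape[0]
    tr = float(np.sum(np.diagonal(B)))
    mu = resolve_mu(tr, n, params.mu)
    if mu <= 0:
        raise InvalidParameterError(
            "mu must be positive: the unregularized Laplacian is singular "
            "(constant vector in its null space)"
        )
    B[np.arange(n), np.arange(n)] += mu
    return Preconditioner(matrix=B, factorization=factorize_spd(B), mu=mu)


def solve_direction(precond: Preconditioner, G: np.ndarray) -> np.ndarray:
    """Spectral direction: solve B P = -G with the cached factorization."""
    G = np.asarray(G, dtype=np.float64)
    if G.shape[0] != precond.matrix.shape[0]:
        raise InvalidInputError("gradient rows do not match preconditioner size")
    return precond.solve(-G)


def line_search(
    X: np.ndarray,
    P: np.ndarray,
    E0: float,
    G: np.ndarray,
    model: AffinityModel,
    params: EEParams,
    alpha_init: float = 1.0,
) -> tuple[float, float]:
    """Armijo backtracking along ``P``.

    Returns the accepted step and new energy.  If no step is accepted after
    the backtracking budget, returns ``(0.0, E0)`` — the caller treats this
    as convergence.
    """
    gdotp = float(np.sum(G * P))
    if gdotp >= 0.0:
        raise InvalidDirectionError(
            f"search direction is not a descent direction (<G,P> = {gdotp:g})"
        )
    alpha = float(alpha_init)
    for _ in range(_MAX_BACKTRACK):
        E_new = energy(X + alpha * P, model, params)
        if E_new <= E0 + _ARMIJO_C * alpha * gdotp:
            return alpha, E_new
        alpha *= _ARMIJO_RHO
    return 0.0, E0


def fit(
    Y_or_model,
    params: EEParams | None = None,
    X0: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> Embedding:
    """Minimize the embedding energy from data or prebuilt affinities.

    When raw data is given, affinities are calibrated at ``params.perplexity``
    (with a temporal term if ``times`` is supplied).  Coordinates start at
    ``X0`` or a seeded small Gaussian.  Iterates gradient -> preconditioned
    solve -> Armijo step until the relative energy change drops below
    ``params.tol`` or ``params.max_iter`` is reached.
    """
    params = params or EEParams()
    if isinstance(Y_or_model, AffinityModel):
        model = Y_or_model
    else:
        model = build_affinities(
            Y_or_model,
            perplexity=params.perplexity,
            times=times,
            temporal_dialect=params.temporal_dialect,
        )
    n = model.n_samples
    rep = repulsive_combination(model, params.beta)
    lam = params.lambda_

    if X0 is None:
        X = initial_coords(n, params.dim, params.seed, params.init_scale)
    else:
        X = np.array(X0, dtype=np.float64)
        if X.shape != (n, params.dim):
            raise InvalidInputError(
                f"X0 must be {n} x {params.dim}, got {X.shape}"
            )

    precond = build_preconditioner(model, params)
    # all global scalars are reduced from per-row partials summed in row
    # order, so a row-partitioned run reproduces these floats exactly
    E_prev = float(np.sum(block_row_energies(X, model.w_p, rep, lam, 0)))
    trace = [E_prev]
    steps: list[float] = []
    converged = False
    reason = "max_iter"
    alpha_prev = 1.0

    for k in range(1, params.max_iter + 1):
        G = block_gradient(X, model.w_p, rep, lam, 0)
        P = precond.solve(-G)
        gdotp = float(np.sum(np.sum(G * P, axis=1)))
        if gdotp >= 0.0:
            converged, reason = True, "stationary point"
            break
        alpha_init = 1.0 if k == 1 else min(1.0, 2.0 * alpha_prev)
        alpha = alpha_init
        E_new = None
        for _ in range(_MAX_BACKTRACK):
            X_trial = X + alpha * P
            E_trial = float(
                np.sum(block_row_energies(X_trial, model.w_p, rep, lam, 0))
            )
            if E_trial <= E_prev + _ARMIJO_C * alpha * gdotp:
                E_new = E_trial
                break
            alpha *= _ARMIJO_RHO
        if E_new is None:
            converged, reason = True, "step failure (line search exhausted)"
            break
        X = X_trial
        trace.append(E_new)
        steps.append(alpha)
        gnorm = float(np.linalg.norm(G))
        logger.debug(
            "iter %d energy %.12g step %.4g |grad| %.4g", k, E_new, alpha, gnorm
        )
        if abs(E_new - E_prev) <= params.tol * abs(E_new):
            converged, reason = True, "energy tolerance"
            E_prev = E_new
            break
        E_prev = E_new
        alpha_prev = alpha

    return Embedding(
        coords=X,
        energy_trace=np.asarray(trace),
        step_trace=np.asarray(steps),
        n_iter=len(steps),
        converged=converged,
        reason=reason,
    )


def relative_error(A: np.ndarray, B: np.ndarray) -> float:
    """||A - B||_F / ||A||_F, the consistency metric between two embeddings."""
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.shape != B.shape:
        raise InvalidInputError(f"shape mismatch: {A.shape} vs {B.shape}")
    denom = float(np.linalg.norm(A))
    if denom == 0.0:
        raise InvalidInputError("relative error undefined for an all-zero reference")
    return float(np.linalg.norm(A - B)) / denom
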