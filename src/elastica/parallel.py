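"""Row-partitioned parallel execution of the embedding algorithm.

The N rows of every pairwise matrix are split into P contiguous, near-equal
blocks; each worker owns its block of the distance, attractive, repulsive and
per-iteration kernel/Laplacian/gradient matrices, while the full data matrix
and the full coordinate matrix are replicated on every worker.  Global
quantities (normalizers, energies, inner products) are computed block-wise
and combined by a reduction in fixed worker-rank order; the coordinate update
and search direction are re-assembled by an all-gather each iteration; the
symmetrization step exchanges transpose blocks between workers.

The backend here executes the worker dataflow in one process, which realizes
the same message-passing semantics (reductions, all-gather, transpose
exchange) without an MPI runtime.  Per-worker bandwidth calibration uses a
warm-start chain local to each block, so block solutions are independent of
other blocks; a single-worker run is bitwise identical to the serial path,
and multi-worker runs agree with it to well below the consistency tolerance.

The one shared component is the linear solver: the regularized attractive
Laplacian is assembled from the worker blocks and factorized once by a solver
service (the role a parallel direct solver plays in a distributed setting);
workers never hold a full pairwise matrix themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from time import perf_counter

import numpy as np
import scipy.linalg

from .affinity import (
    AffinityModel,
    as_values,
    build_temporal,
    calibrate_sigma,
    sigma_order,
    sq_dist_rows,
)
from .exceptions import (
    DegenerateAffinityError,
    DuplicateRowError,
    InvalidParameterError,
)
from ._kernels import block_gradient, block_row_energies
from .optimizer import (
    _ARMIJO_C,
    _ARMIJO_RHO,
    _MAX_BACKTRACK,
    EEParams,
    Embedding,
    energy_rows,
    factorize_spd,
    initial_coords,
    laplacian_rows,
    resolve_mu,
)

__all__ = [
    "Partition",
    "partition_rows",
    "block_sigma_order",
    "WorkerState",
    "ParallelWorkspace",
    "build_workspace",
    "parallel_energy",
    "parallel_fit",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Partition:
    """Contiguous row-block assignment of N rows to P workers."""

    n_rows: int
    n_workers: int
    offsets: tuple[int, ...]

    def block(self, i: int) -> tuple[int, int]:
        return self.offsets[i], self.offsets[i + 1]

    def block_sizes(self) -> tuple[int, ...]:
        return tuple(
            self.offsets[i + 1] - self.offsets[i] for i in range(self.n_workers)
        )


def partition_rows(N: int, P: int) -> Partition:
    """Split N rows into P contiguous blocks whose sizes differ by <= 1.

    The first ``N mod P`` blocks get the extra row.
    """
    if P < 1 or P > N:
        raise InvalidParameterError(f"need 1 <= P <= N, got P={P}, N={N}")
    base, extra = divmod(N, P)
    offsets = [0]
    for i in range(P):
        offsets.append(offsets[-1] + base + (1 if i < extra else 0))
    return Partition(n_rows=N, n_workers=P, offsets=tuple(offsets))


def block_sigma_order(D_block: np.ndarray, block_rows: np.ndarray) -> np.ndarray:
    """Bandwidth-calibration order within one block: the serial greedy
    nearest-neighbor chain restricted to the block's rows.

    Returns global row indices.  With a single worker this reduces exactly to
    the serial order.
    """
    block_rows = np.asarray(block_rows, dtype=np.intp)
    D_sub = D_block[:, block_rows]
    local = sigma_order(D_sub)
    return block_rows[local]


@dataclass
class WorkerState:
    """Matrices owned by one worker: row blocks of every pairwise matrix."""

    rank: int
    start: int
    stop: int
    sigma: np.ndarray = field(default=None)  # type: ignore[assignment]
    wp: np.ndarray = field(default=None)  # type: ignore[assignment]
    wn: np.ndarray = field(default=None)  # type: ignore[assignment]
    rep: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_rows(self) -> int:
        return self.stop - self.start


@dataclass
class ParallelWorkspace:
    """Built per-worker state plus the shared solver service."""

    partition: Partition
    workers: list[WorkerState]
    factorization: tuple
    mu: float
    lam: float
    beta: float


def _calibrate_block(
    D_block: np.ndarray, start: int, stop: int, perplexity: float
) -> np.ndarray:
    rows = np.arange(start, stop)
    order = block_sigma_order(D_block, rows)
    sigma = np.empty(stop - start)
    init = 1.0
    for idx in order:
        local = int(idx) - start
        try:
            s = calibrate_sigma(D_block[local], int(idx), perplexity, init=init)
        except DuplicateRowError:
            logger.warning("row %d duplicates another sample; sigma set to tiny", idx)
            sigma[local] = np.finfo(np.float64).tiny
            continue
        sigma[local] = s
        init = s
    return sigma


def build_workspace(
    Y,
    params: EEParams,
    partition: Partition,
    times: np.ndarray | None = None,
) -> ParallelWorkspace:
    """Run the distributed setup phase: block distances, per-block bandwidth
    calibration, transpose-exchange symmetrization, reduced normalization,
    and one-time factorization of the regularized attractive Laplacian."""
    v = as_values(Y)
    N = v.shape[0]
    part = partition
    P = part.n_workers
    workers = [WorkerState(rank=i, start=part.block(i)[0], stop=part.block(i)[1])
               for i in range(P)]

    # --- Part A: block distances and communication-free sigma calibration.
    D_blocks: list[np.ndarray] = []
    wp_raw: list[np.ndarray] = []
    for w in workers:
        D_b = sq_dist_rows(v[w.start : w.stop], v, w.start)
        w.sigma = _calibrate_block(D_b, w.start, w.stop, params.perplexity)
        inv = 1.0 / (2.0 * w.sigma * w.sigma)
        W_b = np.exp(-D_b * inv[:, None])
        m = w.n_rows
        W_b[np.arange(m), np.arange(w.start, w.stop)] = 0.0
        D_blocks.append(D_b)
        wp_raw.append(W_b)

    # --- Part B: symmetrization via transpose-block exchange, then a
    # global-sum normalization.  Reductions gather per-row partial sums in
    # row order before the final sum, so the normalizer (and every scalar
    # reduced this way) is bitwise identical for any worker count.
    hat_blocks = []
    for w in workers:
        cols = slice(w.start, w.stop)
        hat = np.vstack([wp_raw[j][:, cols] for j in range(P)]).T
        hat_blocks.append(hat)
    rowsum_p = []
    for w, hat in zip(workers, hat_blocks):
        S_b = wp_raw[w.rank] + hat
        wp_raw[w.rank] = S_b
        rowsum_p.append(S_b.sum(axis=1))
    total_p = float(np.sum(np.concatenate(rowsum_p)))
    if total_p == 0.0:
        raise DegenerateAffinityError("all attractive weights are zero")
    for w in workers:
        w.wp = wp_raw[w.rank] / total_p
    del wp_raw, hat_blocks

    # --- Part C: repulsive normalization by a reduced global sum.
    total_n = float(np.sum(np.concatenate([D_b.sum(axis=1) for D_b in D_blocks])))
    if total_n == 0.0:
        raise DegenerateAffinityError("all samples are identical")
    for w, D_b in zip(workers, D_blocks):
        D_b /= total_n
        w.wn = D_b
    del D_blocks

    # Temporal term: cheap O(N^2) matrix, recomputed identically on each
    # worker, then sliced to the owned rows.
    if times is not None:
        T = build_temporal(times, N, dialect=params.temporal_dialect)
        for w in workers:
            w.rep = (
                w.wn if params.beta == 0.0
                else w.wn + params.beta * T[w.start : w.stop]
            )
    else:
        for w in workers:
            w.rep = w.wn

    # --- Part D: attractive Laplacian blocks, assembled and factorized once
    # by the shared solver service.
    B_blocks = [4.0 * laplacian_rows(w.wp, w.start) for w in workers]
    tr = float(np.sum(np.concatenate([
        np.diagonal(B_b, offset=w.start) for w, B_b in zip(workers, B_blocks)
    ])))
    mu = resolve_mu(tr, N, params.mu)
    if mu <= 0:
        raise InvalidParameterError("mu must be positive")
    B = np.vstack(B_blocks)
    del B_blocks
    B[np.arange(N), np.arange(N)] += mu
    fac = factorize_spd(B)
    del B

    return ParallelWorkspace(
        partition=part,
        workers=workers,
        factorization=fac,
        mu=mu,
        lam=params.lambda_,
        beta=params.beta,
    )


def parallel_energy(ws: ParallelWorkspace, X: np.ndarray) -> float:
    """Block-wise energy contributions reduced in worker-rank order."""
    partial = [
        energy_rows(X[w.start : w.stop], X, w.wp, w.rep, ws.lam, w.start)
        for w in ws.workers
    ]
    return sum(partial)


def parallel_fit(
    Y,
    params: EEParams | None = None,
    P: int = 1,
    X0: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> Embedding:
    """Fit the embedding under a P-worker row partition.

    Consistent with the serial path: bitwise identical for P = 1, and within
    the documented relative-error tolerance for P > 1 (the only divergence
    source is the per-block warm-start order of bandwidth calibration and the
    rank-ordered reductions).
    """
    params = params or EEParams()
    v = as_values(Y)
    N = v.shape[0]
    part = partition_rows(N, P)
    ws = build_workspace(v, params, part, times=times)

    if X0 is None:
        X = initial_coords(N, params.dim, params.seed, params.init_scale)
    else:
        X = np.array(X0, dtype=np.float64)

    # Scalar reductions gather per-row partials in row order before summing,
    # mirroring the serial path float for float (see _kernels).
    E_prev = float(np.sum(np.concatenate([
        block_row_energies(X, w.wp, w.rep, ws.lam, w.start) for w in ws.workers
    ])))
    trace = [E_prev]
    steps: list[float] = []
    converged = False
    reason = "max_iter"
    alpha_prev = 1.0

    for k in range(1, params.max_iter + 1):
        G_blocks = []
        worker_times = []
        for w in ws.workers:
            t0 = perf_counter()
            G_blocks.append(block_gradient(X, w.wp, w.rep, ws.lam, w.start))
            worker_times.append(perf_counter() - t0)
        G = np.vstack(G_blocks)  # gather for the solver service
        P_full = scipy.linalg.cho_solve(ws.factorization, -G)
        # all-gather: every worker now holds the full direction (trivial here)
        gdotp = float(np.sum(np.concatenate([
            np.sum(G_blocks[w.rank] * P_full[w.start : w.stop], axis=1)
            for w in ws.workers
        ])))
        if gdotp >= 0.0:
            converged, reason = True, "stationary point"
            break
        alpha_init = 1.0 if k == 1 else min(1.0, 2.0 * alpha_prev)
        alpha = alpha_init
        E_new = None
        for _ in range(_MAX_BACKTRACK):
            X_trial = X + alpha * P_full
            E_trial = float(np.sum(np.concatenate([
                block_row_energies(X_trial, w.wp, w.rep, ws.lam, w.start)
                for w in ws.workers
            ])))
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
        logger.debug(
            "iter %d energy %.12g step %.4g (P=%d, worker ms %s)",
            k, E_new, alpha, P,
            "/".join(f"{t * 1e3:.1f}" for t in worker_times),
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
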