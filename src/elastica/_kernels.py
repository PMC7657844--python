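"""Fused row-block kernels for the optimization hot loop.

These compute the energy and gradient contributions of a contiguous row block
in a single pass over the weight matrices, without materializing the N x N
squared-distance / kernel / reweighted-Laplacian temporaries.  Both the
serial fit (one block covering all rows) and the row-partitioned parallel fit
call the same functions, so a single-worker parallel run stays bitwise
identical to the serial one.

IEEE semantics are kept (no fastmath): results are deterministic.
"""

from __future__ import annotations

import math

import numba
import numpy as np


@numba.njit(cache=True)
def block_row_energies(
    X: np.ndarray,
    wp_rows: np.ndarray,
    rep_rows: np.ndarray,
    lam: float,
    row_offset: int,
) -> np.ndarray:
    """Per-row energy contributions of rows [row_offset, row_offset + m):
    e_i = sum_j wp * d^2 + lam * sum_j rep * exp(-d^2).

    Each entry depends only on its own row, so reductions built from these
    (gathered in row order, then summed) are identical for every worker
    partition — the parallel fit is bitwise consistent with the serial one.
    """
    m = wp_rows.shape[0]
    n = X.shape[0]
    d = X.shape[1]
    out = np.empty(m)
    for i in range(m):
        gi = row_offset + i
        att = 0.0
        rep_e = 0.0
        for j in range(n):
            s = 0.0
            for k in range(d):
                diff = X[gi, k] - X[j, k]
                s += diff * diff
            if j == gi:
                s = 0.0
            att += wp_rows[i, j] * s
            rep_e += rep_rows[i, j] * math.exp(-s)
        out[i] = att + lam * rep_e
    return out


@numba.njit(cache=True)
def block_gradient(
    X: np.ndarray,
    wp_rows: np.ndarray,
    rep_rows: np.ndarray,
    lam: float,
    row_offset: int,
) -> np.ndarray:
    """Gradient rows 4 * sum_j (wp - lam * rep * exp(-d^2)) (x_i - x_j)."""
    m = wp_rows.shape[0]
    n = X.shape[0]
    d = X.shape[1]
    G = np.zeros((m, d))
    for i in range(m):
        gi = row_offset + i
        for j in range(n):
            if j == gi:
                continue
            s = 0.0
            for k in range(d):
                diff = X[gi, k] - X[j, k]
                s += diff * diff
            w = wp_rows[i, j] - lam * rep_rows[i, j] * math.exp(-s)
            for k in range(d):
                G[i, k] += 4.0 * w * (X[gi, k] - X[j, k])
    return G
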