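"""Minimal single-cell preprocessing: filtering, log-normalization,
variable-gene selection and PCA.

The pipeline is ``filter_cells_genes -> lognormalize -> select_variable_genes
-> pca_reduce``.  Filtering drops cells first, then genes (counted on the
surviving cells).  Normalized values are ``ln(count / cell_total * scale + 1)``
with natural log.  Variable genes are ranked by plain variance of the
log-normalized values (a deliberate simple stand-in for variance-stabilizing
selection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .affinity import DataMatrix
from .exceptions import EmptyFilterError, InvalidInputError, InvalidParameterError

__all__ = [
    "CountMatrix",
    "filter_cells_genes",
    "lognormalize",
    "select_variable_genes",
    "pca_reduce",
]


@dataclass
class CountMatrix:
    """Cells x genes nonnegative integer counts with id sidecars."""

    counts: sp.spmatrix | np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        c = self.counts
        if sp.issparse(c):
            c = sp.csr_matrix(c)
        else:
            c = np.asarray(c)
        if c.ndim != 2:
            raise InvalidInputError("counts must be 2-D")
        data = c.data if sp.issparse(c) else c
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise InvalidInputError("counts must be nonnegative integers")
        if len(self.cell_ids) != c.shape[0] or len(self.gene_ids) != c.shape[1]:
            raise InvalidInputError("id lengths must match matrix dimensions")
        self.counts = c

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        c = self.counts
        return np.asarray(c.todense()) if sp.issparse(c) else np.asarray(c)


def filter_cells_genes(
    M: CountMatrix, min_features_per_cell: int, min_cells_per_gene: int
) -> CountMatrix:
    """Drop cells with too few detected genes, then (on the surviving cells)
    genes detected in too few cells."""
    if min_features_per_cell < 0 or min_cells_per_gene < 0:
        raise InvalidParameterError("thresholds must be nonnegative")
    c = M.counts
    detected = (c > 0)
    if sp.issparse(detected):
        feats_per_cell = np.asarray(detected.sum(axis=1)).ravel()
    else:
        feats_per_cell = detected.sum(axis=1)
    keep_cells = feats_per_cell >= min_features_per_cell
    if not keep_cells.any():
        raise EmptyFilterError("no cells pass the feature threshold")
    c2 = c[keep_cells]
    detected2 = (c2 > 0)
    if sp.issparse(detected2):
        cells_per_gene = np.asarray(detected2.sum(axis=0)).ravel()
    else:
        cells_per_gene = detected2.sum(axis=0)
    keep_genes = cells_per_gene >= min_cells_per_gene
    if not keep_genes.any():
        raise EmptyFilterError("no genes pass the cell threshold")
    c3 = c2[:, keep_genes]
    return CountMatrix(
        counts=c3,
        cell_ids=[i for i, k in zip(M.cell_ids, keep_cells) if k],
        gene_ids=[g for g, k in zip(M.gene_ids, keep_genes) if k],
    )


def lognormalize(M: CountMatrix, scale: float = 1e4) -> DataMatrix:
    """ln(count / cell_total * scale + 1), natural log."""
    dense = M.dense().astype(np.float64)
    totals = dense.sum(axis=1)
    if np.any(totals == 0):
        raise InvalidInputError(
            "cells with zero total counts present; run filter_cells_genes first"
        )
    return DataMatrix(np.log1p(dense / totals[:, None] * scale))


def select_variable_genes(
    X: DataMatrix | np.ndarray,
    n_top: int = 2000,
    return_indices: bool = False,
):
    """Keep the ``n_top`` highest-variance columns (ties broken by index,
    column order preserved)."""
    v = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=np.float64)
    if n_top > v.shape[1]:
        raise InvalidParameterError(
            f"n_top={n_top} exceeds the {v.shape[1]} available features"
        )
    var = v.var(axis=0)
    ranked = np.argsort(-var, kind="stable")[:n_top]
    idx = np.sort(ranked)
    out = DataMatrix(v[:, idx])
    return (out, idx) if return_indices else out


def pca_reduce(X: DataMatrix | np.ndarray, n_components: int = 50) -> DataMatrix:
    """Column-centered projection onto the top principal components.

    Sign convention: each component's largest-magnitude loading is positive.
    If the data rank is below ``n_components``, the available components are
    returned with a warning.
    """
    v = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=np.float64)
    n, d = v.shape
    if n_components > min(n - 1, d):
        raise InvalidParameterError(
            f"n_components={n_components} exceeds min(N-1, D)={min(n - 1, d)}"
        )
    centered = v - v.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    tol = S[0] * max(n, d) * np.finfo(np.float64).eps if S.size else 0.0
    rank = int(np.sum(S > tol))
    k = n_components
    if rank < n_components:
        warnings.warn(
            f"data rank {rank} is below n_components={n_components}; "
            "returning the available components",
            RuntimeWarning,
            stacklevel=2,
        )
        k = max(rank, 1)
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    return DataMatrix(U[:, :k] * S[:k])
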