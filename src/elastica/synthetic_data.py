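"""Desk-scale synthetic datasets with the structures the embedding is meant
to reveal: branching trees, separated cluster mixtures, and staged
time-series progressions.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .affinity import DataMatrix
from .exceptions import InvalidParameterError

__all__ = ["LabeledDataset", "make_tree", "make_clusters", "make_timeseries"]


@dataclass(frozen=True)
class LabeledDataset:
    """A data matrix with per-sample labels and optional time stamps."""

    data: DataMatrix
    labels: np.ndarray
    times: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.data.n_samples


def _unit_vector(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def make_tree(
    n_branches: int = 10,
    per_branch: int = 144,
    n_features: int = 60,
    noise_sd: float = 0.1,
    seed: int = 0,
    branch_length: float = 5.0,
) -> LabeledDataset:
    """Tree-structured progression: branch segments splitting off each other.

    Branch 0 is a random unit-direction segment from the origin; every later
    branch starts at a uniformly chosen point along a uniformly chosen
    existing branch and extends in a fresh random direction.  Points sit at
    evenly spaced arc positions plus isotropic Gaussian noise.
    """
    if n_branches < 1:
        raise InvalidParameterError("n_branches must be >= 1")
    rng = np.random.default_rng(seed)
    starts = np.zeros((n_branches, n_features))
    dirs = np.zeros((n_branches, n_features))
    dirs[0] = _unit_vector(rng, n_features)
    for b in range(1, n_branches):
        parent = int(rng.integers(0, b))
        frac = float(rng.uniform())
        starts[b] = starts[parent] + frac * branch_length * dirs[parent]
        dirs[b] = _unit_vector(rng, n_features)
    arc = (np.arange(per_branch) + 0.5) / per_branch * branch_length
    points = np.concatenate(
        [starts[b] + arc[:, None] * dirs[b] for b in range(n_branches)]
    )
    labels = np.repeat(np.arange(n_branches), per_branch)
    noise = rng.standard_normal(points.shape) * noise_sd
    return LabeledDataset(data=DataMatrix(points + noise), labels=labels)


def make_clusters(
    n_samples: int = 4423,
    n_clusters: int = 4,
    n_features: int = 50,
    separation: float = 10.0,
    seed: int = 0,
) -> LabeledDataset:
    """Isotropic unit-variance Gaussian blobs with centers at pairwise
    distance >= ``separation`` and near-equal sizes."""
    if n_clusters < 1:
        raise InvalidParameterError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((n_clusters, n_features))
    if n_clusters > 1:
        scale = 1.0
        while True:
            C = centers * scale
            diff = C[:, None, :] - C[None, :, :]
            d = np.sqrt((diff * diff).sum(-1))
            np.fill_diagonal(d, np.inf)
            if d.min() >= separation:
                centers = C
                break
            scale *= 1.5
    base, extra = divmod(n_samples, n_clusters)
    sizes = [base + (1 if i < extra else 0) for i in range(n_clusters)]
    labels = np.repeat(np.arange(n_clusters), sizes)
    points = centers[labels] + rng.standard_normal((n_samples, n_features))
    return LabeledDataset(data=DataMatrix(points), labels=labels)


def make_timeseries(
    n_stages: int = 39,
    per_stage: int = 30,
    n_features: int = 20,
    dt: float = 0.5,
    seed: int = 0,
    curvature: float = 0.15,
    noise_sd: float = 0.25,
) -> LabeledDataset:
    """Staged samples drifting along a gently curving path.

    Stage ``s`` is an isotropic Gaussian around the path position after ``s``
    unit steps, stamped with time ``s * dt``; the step direction rotates
    slowly (``curvature``), so consecutive stage centroids stay closer than
    stage-skipping ones.
    """
    if n_stages < 2:
        raise InvalidParameterError("n_stages must be >= 2")
    rng = np.random.default_rng(seed)
    direction = _unit_vector(rng, n_features)
    centers = np.zeros((n_stages, n_features))
    for s in range(1, n_stages):
        centers[s] = centers[s - 1] + direction
        turn = rng.standard_normal(n_features) * curvature
        direction = direction + turn
        direction /= np.linalg.norm(direction)
    labels = np.repeat(np.arange(n_stages), per_stage)
    points = centers[labels] + rng.standard_normal(
        (n_stages * per_stage, n_features)
    ) * noise_sd
    times = np.repeat(np.arange(n_stages) * dt, per_stage).astype(np.float64)
    return LabeledDataset(data=DataMatrix(points), labels=labels, times=times)
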