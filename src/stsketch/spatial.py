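"""Spatial weights matrix and embedding smoothing.

W is a sparse row-stochastic n x n matrix averaging each cell over its k
nearest spatial neighbors (optionally including itself, optionally with a
Gaussian kernel). Multiplying any per-cell matrix by W — an embedding, or
the left singular basis U (giving the smoothed basis W U) — blends each
cell's representation with its tissue neighborhood, which is how spatial
context enters expression-space sketchers here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .datasets import STDataset
from .preprocess import Embedding

__all__ = [
    "SpatialWeights",
    "build_spatial_weights",
    "smooth_basis",
    "smoothed_embedding",
]


@dataclass
class SpatialWeights:
    """Row-stochastic kNN averaging matrix over spatial coordinates."""

    W: sp.csr_matrix
    k_neighbors: int
    kernel: str
    self_included: bool

    def __post_init__(self) -> None:
        self.W = sp.csr_matrix(self.W)
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if self.W.nnz and self.W.data.min() < 0:
            raise ValueError("W must be nonnegative")
        rows = np.asarray(self.W.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=1e-8):
            raise ValueError("W rows must sum to 1 (tol 1e-8)")
        max_nnz = np.diff(self.W.indptr).max() if self.W.shape[0] else 0
        if max_nnz > self.k_neighbors + 1:
            raise ValueError("a row has more than k_neighbors + 1 nonzeros")

    @property
    def n(self) -> int:
        return self.W.shape[0]


def build_spatial_weights(
    coords: np.ndarray,
    k_neighbors: int = 15,
    kernel: str = "uniform",
    self_included: bool = True,
) -> SpatialWeights:
    """Build the row-stochastic spatial weights matrix.

    Row ``i`` is supported on cell i's ``k_neighbors`` nearest spatial
    neighbors (exact kd-tree search; ties broken by index), plus itself when
    ``self_included``. ``uniform`` gives equal weights; ``gaussian`` gives
    weights proportional to ``exp(-d^2 / sigma_i^2)`` with ``sigma_i`` the
    distance to the k-th neighbor. Rows are normalized to sum to 1.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 1 <= k_neighbors < n:
        raise ValueError("k_neighbors must satisfy 1 <= k < n")
    if kernel not in ("uniform", "gaussian"):
        raise ValueError(f"unknown kernel {kernel!r}")

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(coords)
    dist, ind = nn.kneighbors(coords)
    # strip each cell from its own neighbor list (duplicate coordinates may
    # shuffle it out of column 0, or off the list entirely): stable-sort self
    # entries to the back, then keep the k nearest of what remains
    self_mask = ind == np.arange(n)[:, None]
    order = np.argsort(self_mask, axis=1, kind="stable")[:, :k_neighbors]
    rows_idx = np.take_along_axis(ind, order, axis=1)
    rows_dist = np.take_along_axis(dist, order, axis=1)

    if self_included:
        rows_idx = np.column_stack((np.arange(n), rows_idx))
        rows_dist = np.column_stack((np.zeros(n), rows_dist))

    if kernel == "uniform":
        weights = np.ones_like(rows_dist)
    else:
        sigma = rows_dist.max(axis=1, keepdims=True)
        sigma[sigma == 0] = 1.0  # duplicate-point neighborhoods
        weights = np.exp(-(rows_dist ** 2) / sigma ** 2)
    weights /= weights.sum(axis=1, keepdims=True)

    m = rows_idx.shape[1]
    W = sp.csr_matrix(
        (weights.ravel(), (np.repeat(np.arange(n), m), rows_idx.ravel())),
        shape=(n, n),
    )
    return SpatialWeights(
        W=W, k_neighbors=k_neighbors, kernel=kernel, self_included=self_included
    )


def smooth_basis(weights: "SpatialWeights | sp.spmatrix", U: np.ndarray) -> np.ndarray:
    """Spatially smooth a basis or score matrix: returns W @ U.

    No re-orthonormalization is applied; columns of the product are in
    general not orthonormal.
    """
    W = weights.W if isinstance(weights, SpatialWeights) else sp.csr_matrix(weights)
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or W.shape[1] != U.shape[0]:
        raise ValueError(
            f"row mismatch: W is {W.shape}, U is {U.shape}"
        )
    return np.asarray(W @ U)


def smoothed_embedding(
    dataset: STDataset, embedding: Embedding, weights: SpatialWeights
) -> Embedding:
    """Smooth an embedding across the tissue: points become W @ points."""
    if embedding.n != dataset.n or weights.n != dataset.n:
        raise ValueError("dataset, embedding and weights must be row-aligned")
    return Embedding(
        points=smooth_basis(weights, embedding.points),
        representation="smoothed_pca",
        row_ids=embedding.row_ids,
    )
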