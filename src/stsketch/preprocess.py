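"""Quality control, normalization and low-rank embedding.

The standard pipeline: drop low-count cells and library-size outliers,
library-size scale + log1p-normalize, then embed to 20 principal components.
A separate randomized SVD of the normalized (uncentered) matrix provides the
left singular basis U used for leverage-score sketching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.utils.extmath import randomized_svd as _sk_randomized_svd

from .datasets import STDataset

__all__ = [
    "Embedding",
    "BasisDecomposition",
    "qc_filter",
    "lognormalize",
    "pca_embedding",
    "randomized_svd",
]

REPRESENTATIONS = ("pca", "coords", "smoothed_pca")


@dataclass
class Embedding:
    """An n x d point set tagged by its representation.

    ``representation`` is one of ``pca`` (principal-component scores),
    ``coords`` (raw spatial coordinates), or ``smoothed_pca`` (scores after
    multiplication by a spatial weights matrix).
    """

    points: np.ndarray
    representation: str
    row_ids: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] < 1:
            raise ValueError("points must be an (n, d) matrix with d >= 1")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("embedding contains non-finite entries")
        if self.representation not in REPRESENTATIONS:
            raise ValueError(
                f"representation must be one of {REPRESENTATIONS}"
            )
        if self.row_ids is not None:
            self.row_ids = np.asarray(self.row_ids, dtype=object)
            if self.row_ids.shape[0] != self.points.shape[0]:
                raise ValueError("row_ids length must match points")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def d(self) -> int:
        return self.points.shape[1]


@dataclass
class BasisDecomposition:
    """Truncated SVD ``X ~ U diag(s) V^T`` with orthonormal-column U."""

    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        r = self.U.shape[1]
        if self.singular_values.shape != (r,) or self.V.shape[1] != r:
            raise ValueError("inconsistent decomposition shapes")
        gram = self.U.T @ self.U
        if not np.allclose(gram, np.eye(r), atol=1e-8):
            raise ValueError("U columns are not orthonormal (tol 1e-8)")
        if np.any(np.diff(self.singular_values) > 1e-12) or np.any(
            self.singular_values < -1e-12
        ):
            raise ValueError("singular values must be nonincreasing and >= 0")

    @property
    def rank(self) -> int:
        return self.U.shape[1]


def qc_filter(
    dataset: STDataset,
    min_counts: int = 100,
    mad_multiplier: float = 5.0,
):
    """Drop low-count cells and library-size outliers.

    A cell is removed iff its total count is below ``min_counts``, or its
    total deviates from the mean total by more than ``mad_multiplier`` times
    the mean absolute deviation (MAD about the mean, two-sided), with the
    mean and MAD computed on the cells passing the first rule.

    Returns ``(filtered_dataset, keep_mask)`` with the mask aligned to the
    input rows and input order preserved.
    """
    if dataset.n == 0:
        raise ValueError("dataset is empty")
    totals = dataset.total_counts()
    pass_min = totals >= min_counts
    n_low = int(np.sum(~pass_min))
    if not np.any(pass_min):
        raise ValueError(
            f"all {dataset.n} cells removed: {n_low} below {min_counts} "
            "counts (outlier rule not reached)"
        )
    center = totals[pass_min].mean()
    mad = np.abs(totals[pass_min] - center).mean()
    keep = pass_min & (np.abs(totals - center) <= mad_multiplier * mad)
    n_out = int(np.sum(pass_min & ~keep))
    if not np.any(keep):
        raise ValueError(
            f"all {dataset.n} cells removed: {n_low} below {min_counts} "
            f"counts, {n_out} library-size outliers "
            f"(> {mad_multiplier} x MAD)"
        )
    return dataset.subset(keep), keep


def lognormalize(counts, scale_target: float = 1e4):
    """Library-size scale and log1p-transform a count matrix.

    Entry ``(i, j)`` becomes ``log(1 + scale_target * c_ij / total_i)``;
    zeros map to zeros, so the sparsity pattern is preserved. Rows with zero
    total are rejected (run :func:`qc_filter` first).
    """
    if scale_target <= 0:
        raise ValueError("scale_target must be positive")
    if sp.issparse(counts):
        counts = counts.tocsr()
        totals = np.asarray(counts.sum(axis=1)).ravel()
        if np.any(totals == 0):
            raise ValueError("zero-total cell encountered; apply qc_filter first")
        out = counts.astype(float)
        row_of = np.repeat(np.arange(out.shape[0]), np.diff(out.indptr))
        out.data = np.log1p(scale_target * out.data / totals[row_of])
        return out
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("zero-total cell encountered; apply qc_filter first")
    return np.log1p(scale_target * counts / totals[:, None])


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        # float32 above ~20M entries keeps peak memory modest
        dtype = np.float32 if X.shape[0] * X.shape[1] > 20_000_000 else float
        return np.asarray(X.todense(), dtype=dtype)
    return np.asarray(X, dtype=float)


def pca_embedding(
    X,
    d: int = 20,
    seed: int = 0,
    row_ids: "np.ndarray | None" = None,
):
    """Truncated PCA of a (normalized) expression matrix.

    Returns ``(embedding, loadings, center)`` where ``loadings`` is the
    ``(g, d)`` component matrix and ``center`` the per-gene mean, so new rows
    project as ``(x - center) @ loadings``. Components are ordered by
    explained variance. Solved exactly via the gene-gene covariance
    eigendecomposition (deterministic); ``seed`` is accepted for interface
    stability and threaded to the solver.
    """
    n, g = X.shape
    if not 1 <= d <= min(n, g):
        raise ValueError(f"d must satisfy 1 <= d <= min(n, g) = {min(n, g)}")
    Xd = _dense(X)
    pca = PCA(n_components=d, svd_solver="covariance_eigh", random_state=seed)
    scores = pca.fit_transform(Xd)
    emb = Embedding(points=scores.astype(float), representation="pca",
                    row_ids=row_ids)
    return emb, pca.components_.T.astype(float), pca.mean_.astype(float)


def randomized_svd(
    X,
    rank: int,
    seed: int = 0,
    oversampling: int = 10,
    power_iterations: int = 4,
) -> BasisDecomposition:
    """Seeded randomized truncated SVD (no centering).

    With a couple of power iterations the top singular values of matrices
    with decaying spectra are reproduced to within a few percent; exact to
    numerical precision when ``rank`` spans the matrix rank.
    """
    n, g = X.shape
    if not 1 <= rank <= min(n, g):
        raise ValueError(f"rank must satisfy 1 <= rank <= {min(n, g)}")
    U, s, Vt = _sk_randomized_svd(
        X,
        n_components=rank,
        n_oversamples=oversampling,
        n_iter=power_iterations,
        random_state=seed,
    )
    return BasisDecomposition(U=U, singular_values=s, V=Vt.T)
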