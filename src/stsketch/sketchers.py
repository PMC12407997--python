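"""Sketching designs: uniform, leverage-score, minimax and maximin.

Each design is exposed two ways:

* a scikit-learn style estimator (``UniformSketcher``, ``LeverageSketcher``,
  ``MinimaxSketcher``, ``MaximinSketcher``) with ``fit(X)`` computing the
  selected row indices as ``indices_`` and ``transform(X)`` returning the
  selected rows, composing with sklearn pipelines and ``get_params`` /
  ``set_params``;
* thin module-level functions (``uniform_sketch``, ``minimax_sketch``, ...)
  matching the benchmark vocabulary, plus a :func:`sketch` dispatcher that
  routes a (method, representation) pair to the right estimator over prepared
  embeddings.

All designs draw ``k = max(1, floor(fraction * n))`` distinct indices and are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .preprocess import Embedding

__all__ = [
    "Sketch",
    "LeverageScores",
    "sketch_size",
    "uniform_sketch",
    "leverage_scores_exact",
    "leverage_scores_approx",
    "probability_sample",
    "minimax_sketch",
    "maximin_sketch",
    "sketch",
    "UniformSketcher",
    "LeverageSketcher",
    "MinimaxSketcher",
    "MaximinSketcher",
    "VALID_PAIRS",
]

METHODS = ("uniform", "leverage", "leverage_smoothed", "minimax", "maximin")
SKETCH_REPRESENTATIONS = ("pca", "coords", "smoothed_pca", "counts")

# valid (method, representation) combinations; uniform ignores the data and
# coordinate-representation uniform sampling is disallowed as redundant
VALID_PAIRS = {
    "uniform": ("counts", "pca", "smoothed_pca"),
    "leverage": ("counts", "pca", "smoothed_pca"),
    "leverage_smoothed": ("smoothed_pca",),
    "minimax": ("pca", "coords", "smoothed_pca"),
    "maximin": ("pca", "coords", "smoothed_pca"),
}


def sketch_size(n: int, fraction: float) -> int:
    """Sketch cardinality rule: ``max(1, floor(fraction * n))``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if n < 1:
        raise ValueError("n must be positive")
    # tiny epsilon so fractions constructed as k/n floor to exactly k
    return max(1, int(np.floor(fraction * n + 1e-9)))


@dataclass
class Sketch:
    """A selected index subset with its provenance."""

    indices: np.ndarray
    method: str
    representation: str
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.ndim != 1:
            raise ValueError("indices must be 1-D")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("sketch indices must be unique")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.representation not in SKETCH_REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")

    @property
    def size(self) -> int:
        return self.indices.shape[0]


@dataclass
class LeverageScores:
    """Per-row leverage scores (squared row norms of a basis)."""

    scores: np.ndarray
    basis_rank: int
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if np.any(self.scores < 0):
            raise ValueError("scores must be nonnegative")


# ---------------------------------------------------------------------------
# score computation and weighted sampling
# ---------------------------------------------------------------------------

def leverage_scores_exact(U: np.ndarray, smoothed: bool = False) -> LeverageScores:
    """Row leverage scores of an orthonormal basis: ``score_i = ||U_i||^2``.

    For column-orthonormal U these are the diagonal of the hat matrix and sum
    to the rank. When ``smoothed`` is true (basis multiplied by a spatial
    weights matrix, hence no longer orthonormal) the raw squared row norms
    are used as-is and the orthonormality check is skipped.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("U must be 2-D")
    r = U.shape[1]
    if not smoothed:
        gram = U.T @ U
        if not np.allclose(gram, np.eye(r), atol=1e-6):
            raise ValueError(
                "U is not column-orthonormal (tol 1e-6); pass smoothed=True "
                "to score a non-orthonormal basis"
            )
    return LeverageScores(
        scores=np.einsum("ij,ij->i", U, U), basis_rank=r, smoothed=smoothed
    )


def leverage_scores_approx(
    X,
    rank: int,
    seed: int = 0,
    oversampling: int = 10,
) -> LeverageScores:
    """Approximate leverage scores of a large matrix via sketch-and-QR.

    Projects X against a seeded Gaussian test matrix of width
    ``rank + oversampling``, orthonormalizes the projection with a thin QR,
    and scores rows by squared norm in the orthonormal factor. Exact (up to
    numerics) whenever X has rank <= the projection width.
    """
    n, g = X.shape
    if not 1 <= rank <= min(n, g):
        raise ValueError(f"rank must satisfy 1 <= rank <= {min(n, g)}")
    rng = np.random.default_rng(seed)
    width = min(rank + oversampling, g)
    omega = rng.standard_normal((g, width))
    Y = np.asarray(X @ omega)
    # pivoted QR so a rank-deficient projection is truncated to its numerical
    # column space instead of padded with arbitrary orthogonal directions
    Q, R, _ = scipy.linalg.qr(Y, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    r_eff = int(np.sum(diag > max(Y.shape) * np.finfo(float).eps * diag.max())) \
        if diag.size and diag.max() > 0 else 1
    Q = Q[:, :max(1, r_eff)]
    return LeverageScores(
        scores=np.einsum("ij,ij->i", Q, Q), basis_rank=Q.shape[1], smoothed=False
    )


def probability_sample(
    scores: "LeverageScores | np.ndarray", k: int, seed: int = 0
) -> np.ndarray:
    """Draw k distinct indices with probability proportional to score.

    Sampling is without replacement, equivalent to sequential renormalized
    draws (probability-proportional-to-size successive sampling), realized
    with exponential race keys for speed: index i gets key ``E_i / score_i``
    with ``E_i ~ Exp(1)``, and the k smallest keys win. Deterministic per
    seed; zero-score rows can never be drawn.
    """
    w = scores.scores if isinstance(scores, LeverageScores) else np.asarray(
        scores, dtype=float
    )
    if np.any(w < 0):
        raise ValueError("scores must be nonnegative")
    support = np.flatnonzero(w > 0)
    if k > support.size:
        raise ValueError(
            f"cannot draw {k} items from {support.size} positive-score rows"
        )
    rng = np.random.default_rng(seed)
    keys = np.full(w.shape[0], np.inf)
    keys[support] = rng.exponential(size=w.shape[0])[support] / w[support]
    return np.argsort(keys, kind="stable")[:k]


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class _BaseSketcher(BaseEstimator):
    """Common fit/transform machinery for row-subset sketchers."""

    def __init__(self, fraction: float = 0.1, random_state: "int | None" = None):
        self.fraction = fraction
        self.random_state = random_state

    def _seed(self) -> int:
        return 0 if self.random_state is None else int(self.random_state)

    def fit(self, X, y=None):
        X = check_array(X, accept_sparse="csr")
        k = sketch_size(X.shape[0], self.fraction)
        self.n_samples_in_ = X.shape[0]
        self.n_features_in_ = X.shape[1]
        self.indices_ = np.asarray(self._select(X, k), dtype=int)
        return self

    def transform(self, X):
        """Return the sketched rows of X (row subset, features unchanged)."""
        check_is_fitted(self, "indices_")
        X = check_array(X, accept_sparse="csr")
        if X.shape[0] != self.n_samples_in_:
            raise ValueError(
                f"X has {X.shape[0]} rows; sketch was fitted on "
                f"{self.n_samples_in_}"
            )
        return X[self.indices_]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        """Boolean mask of selected rows."""
        check_is_fitted(self, "indices_")
        mask = np.zeros(self.n_samples_in_, dtype=bool)
        mask[self.indices_] = True
        return mask

    def _select(self, X, k):  # pragma: no cover - abstract
        raise NotImplementedError


class UniformSketcher(_BaseSketcher):
    """Uniform random sketch: k distinct rows with equal probability."""

    def _select(self, X, k):
        rng = np.random.default_rng(self._seed())
        return rng.choice(X.shape[0], size=k, replace=False)


class LeverageSketcher(_BaseSketcher):
    """Leverage-score sketch: rows drawn proportional to their influence.

    ``mode`` selects how scores are obtained from the fitted matrix:

    - ``"exact"``: orthonormalize the columns of X (thin QR) and take squared
      row norms — the hat-matrix diagonal of X's column space. Intended for
      narrow inputs (an embedding or singular basis).
    - ``"raw"``: squared row norms of X as-is; for spatially smoothed bases
      ``W U`` whose columns are deliberately not re-orthonormalized.
    - ``"approx"``: randomized projection + QR for wide matrices
      (cell-by-gene), rank ``rank`` plus ``oversampling``.
    """

    def __init__(
        self,
        fraction: float = 0.1,
        mode: str = "exact",
        rank: int = 20,
        oversampling: int = 10,
        random_state: "int | None" = None,
    ):
        super().__init__(fraction=fraction, random_state=random_state)
        self.mode = mode
        self.rank = rank
        self.oversampling = oversampling

    def _select(self, X, k):
        seed = self._seed()
        if self.mode == "exact":
            Q, _ = np.linalg.qr(np.asarray(X.todense() if sp.issparse(X) else X,
                                           dtype=float))
            lev = leverage_scores_exact(Q)
        elif self.mode == "raw":
            Xd = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
            lev = leverage_scores_exact(Xd, smoothed=True)
        elif self.mode == "approx":
            lev = leverage_scores_approx(
                X, rank=self.rank, seed=_spawn(seed, 1),
                oversampling=self.oversampling,
            )
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        self.leverage_scores_ = lev
        return probability_sample(lev, k, seed=_spawn(seed, 2))


class MinimaxSketcher(_BaseSketcher):
    """Grid-accelerated minimax (Hausdorff-coverage) sketch.

    Binary-searches a lattice cell width so the number of occupied hypercubes
    covering the points is minimal while still >= k, then draws k occupied
    cells without replacement (all of them when the count allows) and one
    uniformly random member from each — approximate farthest-point coverage
    at grid resolution. If even the finest width yields fewer than k occupied
    cells (duplicate points), the sketch is completed farthest-first.
    """

    def __init__(
        self,
        fraction: float = 0.1,
        n_search_iter: int = 30,
        random_state: "int | None" = None,
    ):
        super().__init__(fraction=fraction, random_state=random_state)
        self.n_search_iter = n_search_iter

    @staticmethod
    def _cell_inverse(X, mins, width):
        ids = np.floor((X - mins) / width).astype(np.int64)
        _, inverse = np.unique(ids, axis=0, return_inverse=True)
        return inverse.reshape(-1)

    def _select(self, X, k):
        X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
        n = X.shape[0]
        rng = np.random.default_rng(self._seed())
        mins = X.min(axis=0)
        diag = float(np.linalg.norm(X.max(axis=0) - mins))
        if diag == 0.0:  # all points identical
            return rng.choice(n, size=k, replace=False)

        # larger width -> fewer occupied cells; search for the width whose
        # occupied count is the smallest value still >= k (ties toward
        # smaller width via the >= branch recording before moving lo up)
        lo, hi = 0.0, diag
        best = None  # (occupied_count, width, inverse)
        for _ in range(self.n_search_iter):
            mid = (lo + hi) / 2.0
            if mid <= 0.0:
                break
            inverse = self._cell_inverse(X, mins, mid)
            occ = int(inverse.max()) + 1
            if occ >= k:
                if best is None or occ < best[0]:
                    best = (occ, mid, inverse)
                lo = mid
            else:
                hi = mid
        if best is None:  # duplicates: fall back to finest grid seen
            inverse = self._cell_inverse(X, mins, diag * 2 ** -self.n_search_iter)
            best = (int(inverse.max()) + 1, None, inverse)

        occ, _, inverse = best
        chosen_cells = (
            np.arange(occ) if occ <= k
            else rng.choice(occ, size=k, replace=False)
        )
        order = np.argsort(inverse, kind="stable")
        bounds = np.searchsorted(inverse[order], np.arange(occ + 1))
        picks = []
        for c in chosen_cells:
            members = order[bounds[c]:bounds[c + 1]]
            picks.append(members[rng.integers(members.size)])
        picks = np.array(sorted(set(picks)), dtype=int)
        if picks.size < k:
            picks = _farthest_first_complete(X, picks, k, rng)
        return picks


class MaximinSketcher(_BaseSketcher):
    """Greedy maximin (farthest-first) sketch.

    Starts from a uniformly random point, then repeatedly adds the point
    farthest from the current sketch (argmax of the minimum distance to
    selected points; ties resolved to the lowest index). The greedy traversal
    is the classic 2-approximation of the maximin design.
    """

    def _select(self, X, k):
        X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
        rng = np.random.default_rng(self._seed())
        start = int(rng.integers(X.shape[0]))
        return _farthest_first_complete(X, np.array([start]), k, rng)


def _farthest_first_complete(X, selected, k, rng) -> np.ndarray:
    """Extend ``selected`` to size k by farthest-first traversal."""
    selected = list(np.asarray(selected, dtype=int))
    if not selected:
        selected = [int(rng.integers(X.shape[0]))]
    mind = np.full(X.shape[0], np.inf)
    for j in selected:
        mind = np.minimum(mind, np.linalg.norm(X - X[j], axis=1))
    mind[selected] = -np.inf  # never re-pick, even among duplicate points
    while len(selected) < k:
        j = int(np.argmax(mind))  # first max = lowest index on ties
        selected.append(j)
        mind = np.minimum(mind, np.linalg.norm(X - X[j], axis=1))
        mind[j] = -np.inf
    return np.asarray(selected, dtype=int)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def _spawn(seed: int, key: int) -> int:
    """Derive a 31-bit child seed for an independent random stream."""
    return int(
        np.random.SeedSequence(entropy=seed, spawn_key=(key,)).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def uniform_sketch(n: int, fraction: float, seed: int = 0) -> Sketch:
    """Uniform random sketch of ``max(1, floor(fraction * n))`` indices."""
    k = sketch_size(n, fraction)
    rng = np.random.default_rng(seed)
    return Sketch(
        indices=rng.choice(n, size=k, replace=False),
        method="uniform", representation="counts", fraction=fraction, seed=seed,
    )


def minimax_sketch(embedding: "Embedding | np.ndarray", k: int, seed: int = 0) -> Sketch:
    pts, rep = _points_of(embedding)
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must satisfy 1 <= k <= n")
    est = MinimaxSketcher(fraction=k / n, random_state=seed)
    est.fit(pts)
    idx = est.indices_[:k] if est.indices_.size > k else est.indices_
    return Sketch(indices=idx, method="minimax", representation=rep,
                  fraction=k / n, seed=seed)


def maximin_sketch(embedding: "Embedding | np.ndarray", k: int, seed: int = 0) -> Sketch:
    pts, rep = _points_of(embedding)
    n = pts.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must satisfy 1 <= k <= n")
    est = MaximinSketcher(fraction=k / n, random_state=seed)
    est.fit(pts)
    return Sketch(indices=est.indices_, method="maximin", representation=rep,
                  fraction=k / n, seed=seed)


def _points_of(embedding):
    if isinstance(embedding, Embedding):
        return embedding.points, embedding.representation
    return np.asarray(embedding, dtype=float), "pca"


def sketch(
    dataset,
    method: str,
    representation: str,
    fraction: float,
    seed: int = 0,
    context: "dict | None" = None,
) -> Sketch:
    """Dispatch a (method, representation) pair over prepared inputs.

    ``context`` carries whatever the pair needs, as produced by
    :func:`stsketch.benchmark.prepare_context`:

    - ``"pca"``, ``"coords"``, ``"smoothed_pca"``: :class:`Embedding` objects
      (minimax / maximin operate on these point sets);
    - ``"basis"``: :class:`BasisDecomposition` of the normalized matrix
      (leverage x pca scores the orthonormal U exactly);
    - ``"smoothed_basis"``: the matrix ``W U`` (leverage x smoothed_pca /
      leverage_smoothed scores its raw squared row norms);
    - ``"normalized"``: normalized cell-by-gene matrix (leverage x counts
      approximates scores by random projection + QR).

    Uniform sampling ignores the data; its coordinate representation is
    rejected as redundant (on a regular grid it is plain uniform sampling).
    """
    context = context or {}
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if representation not in VALID_PAIRS.get(method, ()):
        raise ValueError(
            f"unsupported configuration ({method}, {representation}); "
            f"valid pairs: "
            + "; ".join(f"{m} x {{{', '.join(r)}}}" for m, r in VALID_PAIRS.items())
        )
    n = dataset.n
    k = sketch_size(n, fraction)

    if method == "uniform":
        sk = uniform_sketch(n, fraction, seed)
        return Sketch(indices=sk.indices, method="uniform",
                      representation=representation, fraction=fraction, seed=seed)

    if method in ("leverage", "leverage_smoothed"):
        if method == "leverage_smoothed" or representation == "smoothed_pca":
            smoothed = _require(context, "smoothed_basis", method, representation)
            lev = leverage_scores_exact(np.asarray(smoothed), smoothed=True)
        elif representation == "pca":
            basis = _require(context, "basis", method, representation)
            lev = leverage_scores_exact(basis.U)
        else:  # counts
            X = _require(context, "normalized", method, representation)
            rank = context.get("rank", 20)
            lev = leverage_scores_approx(X, rank=rank, seed=_spawn(seed, 1))
        idx = probability_sample(lev, k, seed=_spawn(seed, 2))
        return Sketch(indices=idx, method=method, representation=representation,
                      fraction=fraction, seed=seed)

    emb = _require(context, representation, method, representation)
    fn = minimax_sketch if method == "minimax" else maximin_sketch
    sk = fn(emb, k, seed=seed)
    return Sketch(indices=sk.indices, method=method, representation=representation,
                  fraction=fraction, seed=seed)


def _require(context, key, method, representation):
    if key not in context:
        raise ValueError(
            f"({method}, {representation}) requires context[{key!r}]"
        )
    return context[key]
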