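"""Sketch evaluation metrics.

Five complementary criteria quantify how faithfully a sketch represents the
full dataset:

* robust (partial) directed Hausdorff distance, in expression space and in
  physical coordinate space — coverage: the q-quantile of each full point's
  distance to its nearest sketched point;
* adjusted Rand index between clusters derived from the sketch and reference
  labels (ground truth when available, full-data graph clusters otherwise);
* PCA projection difference — drift between projections onto components
  learned from the full data versus components learned from the sketch;
* local neighborhood distortion — mean squared error between kNN cell-type
  proportion vectors computed in the full versus sketched populations;
* an overall spatial score rank-summing ARI, coordinate Hausdorff and
  neighborhood distortion at a fixed sampling fraction (lower = better).
"""

from __future__ import annotations

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .datasets import STDataset
from .preprocess import Embedding
from .sketchers import Sketch

__all__ = [
    "partial_hausdorff",
    "cluster_for_ari",
    "adjusted_rand_index",
    "pca_projection_difference",
    "neighborhood_composition",
    "neighborhood_mse",
    "rank_sum_score",
    "METRIC_NAMES",
]

METRIC_NAMES = (
    "hausdorff_expr", "hausdorff_coord", "ari", "pca_diff", "neighborhood_mse"
)
SPATIAL_SCORE_METRICS = ("ari", "hausdorff_coord", "neighborhood_mse")


def _as_points(x) -> np.ndarray:
    pts = x.points if isinstance(x, Embedding) else np.asarray(x, dtype=float)
    if pts.ndim != 2:
        raise ValueError("expected an (n, d) point matrix")
    return pts


def _nn(points, n_neighbors):
    # kd-trees degrade in high dimension; brute force is faster there and
    # exact everywhere
    algo = "brute" if points.shape[1] > 3 else "auto"
    return NearestNeighbors(n_neighbors=n_neighbors, algorithm=algo).fit(points)


def partial_hausdorff(full_points, sketch_points, q: float = 1.0) -> float:
    """Directed partial Hausdorff distance from the full set to the sketch.

    The distance of every full point to its nearest sketched point is
    computed exactly, and the q-quantile returned; ``q=1`` gives the classic
    directed Hausdorff maximum, smaller q trims outlier sensitivity.
    """
    full = _as_points(full_points)
    sketch = _as_points(sketch_points)
    if sketch.shape[0] < 1:
        raise ValueError("sketch must contain at least one point")
    if not 0.0 < q <= 1.0:
        raise ValueError("q must lie in (0, 1]")
    dists, _ = _nn(sketch, 1).kneighbors(full)
    dists = dists.ravel()
    return float(dists.max()) if q == 1.0 else float(np.quantile(dists, q))


def _snn_graph(points: np.ndarray, k: int) -> ig.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights."""
    n = points.shape[0]
    k = min(k, n - 1)
    _, ind = _nn(points, k + 1).kneighbors(points)  # includes self
    rows = np.repeat(np.arange(n), k + 1)
    A = sp.csr_matrix(
        (np.ones(n * (k + 1)), (rows, ind.ravel())), shape=(n, n)
    )
    pattern = ((A + A.T) > 0).astype(float)
    shared = (A @ A.T).multiply(pattern).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2 * (k + 1) - s)
    keep = jac > 0
    g = ig.Graph(
        n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist()))
    )
    g.es["weight"] = jac[keep].tolist()
    return g


def cluster_for_ari(
    embedding: "Embedding | np.ndarray",
    resolution: float = 1.0,
    seed: int = 0,
    k: int = 15,
) -> np.ndarray:
    """Graph-based clustering of an embedding (SNN + Leiden modularity).

    Builds a shared-nearest-neighbor graph (k=15 by default, Jaccard
    weights) and optimizes the RB-configuration modularity at the given
    resolution with a seeded Leiden run. Returns integer community labels.
    """
    pts = _as_points(embedding)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points to cluster")
    g = _snn_graph(pts, k)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight" if g.ecount() else None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def adjusted_rand_index(a, b) -> float:
    """Pair-counting agreement between two labelings, adjusted for chance."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def pca_projection_difference(
    full_loadings: np.ndarray,
    full_center: np.ndarray,
    sketch_matrix,
    d: "int | None" = None,
    seed: int = 0,
) -> float:
    """Drift between full-data and sketch-learned principal subspaces.

    Projects the sketched rows onto the full data's loadings, refits a fresh
    d-component PCA on the sketch alone, aligns each sketch component's sign
    to the full projection (sign of the per-column inner product; no
    rotation, so genuine loading drift is not masked), and returns the mean
    Euclidean distance between the paired projections.
    """
    loadings = np.asarray(full_loadings, dtype=float)
    if d is None:
        d = loadings.shape[1]
    Xs = np.asarray(
        sketch_matrix.todense() if sp.issparse(sketch_matrix) else sketch_matrix,
        dtype=float,
    )
    m = Xs.shape[0]
    if m <= d:
        raise ValueError(f"sketch has {m} rows; need more than d={d}")
    P_full = (Xs - np.asarray(full_center, dtype=float)) @ loadings[:, :d]
    pca = PCA(n_components=d, svd_solver="covariance_eigh", random_state=seed)
    P_sketch = pca.fit_transform(Xs)
    signs = np.sign(np.einsum("ij,ij->j", P_sketch, P_full))
    signs[signs == 0] = 1.0
    return float(np.linalg.norm(P_full - P_sketch * signs, axis=1).mean())


def neighborhood_composition(
    coords: np.ndarray,
    labels: np.ndarray,
    query: np.ndarray,
    k: int,
    categories: "np.ndarray | None" = None,
):
    """Label proportions over each query cell's k nearest spatial neighbors.

    The population is the full set of rows of ``coords``; ``query`` indexes
    into it. A cell is not its own neighbor. Returns ``(props, categories)``
    with ``props`` of shape ``(len(query), len(categories))``, rows summing
    to 1.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    query = np.asarray(query, dtype=int)
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the population ({n})")
    if categories is None:
        categories = np.unique(labels)
    cat_index = {c: i for i, c in enumerate(categories)}
    codes = np.array([cat_index[l] for l in labels], dtype=int)

    _, ind = _nn(coords, k + 1).kneighbors(coords[query])
    # drop self when present, else the farthest of the k+1
    self_mask = ind == query[:, None]
    order = np.argsort(self_mask, axis=1, kind="stable")[:, :k]
    neigh = np.take_along_axis(ind, order, axis=1)

    props = np.zeros((query.shape[0], len(categories)))
    for j, c in enumerate(range(len(categories))):
        props[:, j] = (codes[neigh] == c).mean(axis=1)
    return props, np.asarray(categories)


def neighborhood_mse(dataset: STDataset, sketch: Sketch, k: int = 20) -> float:
    """Local neighborhood distortion of a sketch.

    For every sketched cell, its kNN label-proportion vector is computed in
    the full population and again within the sketched population, and the
    squared differences are averaged over label categories and cells.
    Bounded above by 2.
    """
    if dataset.labels is None:
        raise ValueError("dataset must carry labels")
    idx = sketch.indices
    if idx.shape[0] <= k:
        raise ValueError(f"sketch size {idx.shape[0]} must exceed k={k}")
    cats = np.unique(dataset.labels)
    full_props, _ = neighborhood_composition(
        dataset.coords, dataset.labels, idx, k, categories=cats
    )
    sk_props, _ = neighborhood_composition(
        dataset.coords[idx], dataset.labels[idx],
        np.arange(idx.shape[0]), k, categories=cats,
    )
    return float(np.mean((full_props - sk_props) ** 2, axis=1).mean())


def rank_sum_score(
    records: pd.DataFrame, score_fraction: "float | None" = None
) -> pd.DataFrame:
    """Rank conditions per metric and sum the three spatial ranks.

    ``records`` is the long-form metric table (columns: method,
    representation, fraction, replicate, metric, value). Replicates are
    averaged first; within each metric column rank 1 is best (highest ARI,
    lowest for every distance/error metric) with average ranks on ties. The
    overall spatial score is the sum of the ARI, coordinate-Hausdorff and
    neighborhood-MSE ranks — lower is better.
    """
    df = records
    if score_fraction is not None:
        df = df[np.isclose(df["fraction"], score_fraction)]
    if df.empty:
        raise ValueError("no records at the requested fraction")
    mean_vals = (
        df.groupby(["method", "representation", "metric"], sort=True)["value"]
        .mean()
        .unstack("metric")
    )
    missing = [m for m in SPATIAL_SCORE_METRICS if m not in mean_vals.columns
               or mean_vals[m].isna().any()]
    if missing:
        raise ValueError(f"missing spatial metric(s) for some condition: {missing}")
    table = pd.DataFrame(index=mean_vals.index)
    for metric in mean_vals.columns:
        ascending = metric != "ari"  # high ARI is good, low everything else
        table[f"rank_{metric}"] = mean_vals[metric].rank(
            ascending=ascending, method="average"
        )
        table[metric] = mean_vals[metric]
    table["overall_spatial_score"] = sum(
        table[f"rank_{m}"] for m in SPATIAL_SCORE_METRICS
    )
    return table
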