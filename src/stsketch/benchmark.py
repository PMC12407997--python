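"""Benchmark orchestration: methods x representations x fractions x replicates.

`run_benchmark` preprocesses a dataset once (QC, log-normalization, PCA,
randomized-SVD basis, spatial weights, smoothed variants), draws every
requested sketch, scores each with the five evaluation metrics, and
aggregates an overall spatial rank table at one reference fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import STDataset
from .metrics import (
    METRIC_NAMES,
    adjusted_rand_index,
    cluster_for_ari,
    neighborhood_mse,
    partial_hausdorff,
    pca_projection_difference,
    rank_sum_score,
)
from .preprocess import Embedding, lognormalize, pca_embedding, qc_filter, randomized_svd
from .sketchers import VALID_PAIRS, sketch
from .spatial import build_spatial_weights, smooth_basis, smoothed_embedding

__all__ = ["BenchmarkConfig", "DEFAULT_CONDITIONS", "prepare_context", "run_benchmark"]

logger = logging.getLogger(__name__)

# the benchmark's standard condition set (method, representation)
DEFAULT_CONDITIONS = (
    ("uniform", "counts"),
    ("leverage", "counts"),
    ("leverage", "pca"),
    ("leverage_smoothed", "smoothed_pca"),
    ("minimax", "pca"),
    ("minimax", "coords"),
    ("minimax", "smoothed_pca"),
    ("maximin", "pca"),
    ("maximin", "coords"),
    ("maximin", "smoothed_pca"),
)


@dataclass
class BenchmarkConfig:
    """Experiment matrix and shared metric parameters."""

    conditions: "tuple | None" = None  # None -> DEFAULT_CONDITIONS
    fractions: tuple = (0.01, 0.02, 0.05, 0.1, 0.2)
    replicates: int = 10
    base_seed: int = 0
    score_fraction: float = 0.1
    hausdorff_q: float = 0.99
    knn_k: int = 20
    n_pcs: int = 20
    weights_k: int = 15
    weights_kernel: str = "uniform"
    cluster_resolution: float = 1.0
    cluster_k: int = 15
    min_counts: int = 100
    mad_multiplier: float = 5.0
    scale_target: float = 1e4
    skip_coords_on_grid: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if not any(np.isclose(self.score_fraction, f) for f in self.fractions):
            raise ValueError("score_fraction must be one of fractions")
        conds = DEFAULT_CONDITIONS if self.conditions is None else tuple(
            tuple(c) for c in self.conditions
        )
        for method, rep in conds:
            if rep not in VALID_PAIRS.get(method, ()):
                raise ValueError(
                    f"invalid condition ({method}, {rep}); valid pairs: "
                    + "; ".join(f"{m} x {r}" for m, r in VALID_PAIRS.items())
                )
        self.conditions = conds


def prepare_context(dataset: STDataset, cfg: BenchmarkConfig):
    """Run shared preprocessing once; returns (filtered dataset, context).

    The context dict carries everything any sketcher or metric needs:
    normalized matrix, PCA embedding + loadings + center, rSVD basis U,
    spatial weights W, the smoothed basis W U and smoothed embedding, and
    the reference labels for ARI (ground truth if present, else a seeded
    full-data graph clustering).
    """
    filtered, keep = qc_filter(dataset, cfg.min_counts, cfg.mad_multiplier)
    normalized = lognormalize(filtered.counts, cfg.scale_target)
    d = min(cfg.n_pcs, filtered.n - 1, filtered.n_genes)
    pca_emb, loadings, center = pca_embedding(
        normalized, d=d, seed=cfg.base_seed, row_ids=filtered.ids
    )
    basis = randomized_svd(normalized, rank=d, seed=cfg.base_seed)
    weights = build_spatial_weights(
        filtered.coords, k_neighbors=min(cfg.weights_k, filtered.n - 1),
        kernel=cfg.weights_kernel,
    )
    context = {
        "normalized": normalized,
        "rank": d,
        "pca": pca_emb,
        "loadings": loadings,
        "center": center,
        "basis": basis,
        "weights": weights,
        "smoothed_basis": smooth_basis(weights, basis.U),
        "coords": Embedding(filtered.coords, "coords", row_ids=filtered.ids),
        "smoothed_pca": smoothed_embedding(filtered, pca_emb, weights),
        "keep_mask": keep,
    }
    if filtered.labels is not None:
        context["reference_labels"] = filtered.labels
    else:
        logger.info("no ground-truth labels; clustering full data for reference")
        context["reference_labels"] = cluster_for_ari(
            pca_emb, resolution=cfg.cluster_resolution,
            seed=cfg.base_seed, k=cfg.cluster_k,
        )
    return filtered, context


def _sketch_metrics(filtered, context, sk, cfg, seed) -> dict:
    """All five metrics for one sketch."""
    idx = sk.indices
    pca_pts = context["pca"].points
    values = {
        "hausdorff_expr": partial_hausdorff(
            pca_pts, pca_pts[idx], q=cfg.hausdorff_q
        ),
        "hausdorff_coord": partial_hausdorff(
            filtered.coords, filtered.coords[idx], q=cfg.hausdorff_q
        ),
    }
    # sketch-derived clusters: fresh PCA of the sketch's own normalized rows
    Xs = context["normalized"][idx]
    d = min(cfg.n_pcs, idx.shape[0] - 1, filtered.n_genes)
    sk_emb, _, _ = pca_embedding(Xs, d=d, seed=seed)
    sk_clusters = cluster_for_ari(
        sk_emb, resolution=cfg.cluster_resolution, seed=seed, k=cfg.cluster_k
    )
    ref = np.asarray(context["reference_labels"])[idx]
    values["ari"] = adjusted_rand_index(sk_clusters, ref)
    values["pca_diff"] = pca_projection_difference(
        context["loadings"], context["center"], Xs, d=d, seed=seed
    )
    labelled = STDataset(
        counts=filtered.counts, coords=filtered.coords,
        labels=np.asarray(context["reference_labels"]), ids=filtered.ids,
    )
    k_mse = min(cfg.knn_k, idx.shape[0] - 1)
    values["neighborhood_mse"] = neighborhood_mse(labelled, sk, k=k_mse)
    return values


def run_benchmark(dataset: STDataset, cfg: "BenchmarkConfig | None" = None):
    """Run the full experiment matrix on one dataset.

    Returns ``(records, rank_table)``: the long-form metric table with one
    row per (condition, fraction, replicate, metric), and the rank-sum
    summary at ``cfg.score_fraction``. Replicate ``r`` uses seed
    ``base_seed + r`` for every stochastic stage, so reruns with the same
    configuration are identical.
    """
    cfg = cfg or BenchmarkConfig()
    filtered, context = prepare_context(dataset, cfg)
    rows = []
    for method, rep in cfg.conditions:
        if cfg.skip_coords_on_grid and rep == "coords":
            logger.warning(
                "skipping (%s, coords): coordinate sketching on a regular "
                "grid is akin to uniform sampling", method,
            )
            continue
        for fraction in cfg.fractions:
            for r in range(cfg.replicates):
                seed = cfg.base_seed + r
                sk = sketch(filtered, method, rep, fraction, seed=seed,
                            context=context)
                values = _sketch_metrics(filtered, context, sk, cfg, seed)
                for metric in METRIC_NAMES:
                    rows.append(
                        {
                            "method": method,
                            "representation": rep,
                            "fraction": fraction,
                            "replicate": r,
                            "metric": metric,
                            "value": values[metric],
                        }
                    )
                logger.info(
                    "%s x %s f=%.3g rep=%d done", method, rep, fraction, r
                )
    records = pd.DataFrame(rows)
    rank_table = rank_sum_score(records, score_fraction=cfg.score_fraction)
    return records, rank_table
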