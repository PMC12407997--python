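"""Synthetic spatial transcriptomics generator.

Emulates two measurement geometries — Visium-like regular grids and
Xenium-like random per-cell coordinates — carrying one of three spatial
domain layouts (vertical stripes, concentric annuli, or an irregular
Voronoi mosaic of domains). Expression follows a zero-inflated negative
binomial: each gene has a log-normal baseline mean, each domain class owns a
disjoint block of signal genes whose means are multiplied by a class-specific
fold change, counts are NB-distributed around those means and then zeroed
independently with a fixed dropout probability.

Defaults target an imaging-ST count regime: 100,000 locations x 500 genes,
six classes "A".."F" with 25 signal genes each, baseline mean 0.5 transcripts
per gene, NB size 2, 20% zero inflation, and fold changes spread over [2, 8].
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .datasets import STDataset

__all__ = [
    "SimulationConfig",
    "generate_coordinates",
    "assign_domain_labels",
    "simulate_counts",
    "make_dataset",
    "make_rare_state_dataset",
]

# rows per chunk when sampling the count matrix; fixed so the RNG stream
# (hence the dataset) is independent of available memory
_CHUNK_ROWS = 16384

# Voronoi seeds per class in the "complex" layout
_VORONOI_SEEDS_PER_CLASS = 3


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive independent 31-bit integer seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    ``layout`` controls the measurement geometry (``grid`` = Visium-like,
    ``random`` = Xenium-like); ``pattern`` the spatial arrangement of the
    domain classes. ``dispersion`` is the NB size parameter under the
    mean/size convention (variance = mu + mu^2/size).
    """

    n_locations: int = 100_000
    n_genes: int = 500
    layout: str = "grid"
    pattern: str = "complex"
    n_classes: int = 6
    n_signal_genes_per_class: int = 25
    baseline_log_mean: float = float(np.log(0.5))
    baseline_log_sd: float = 1.0
    dispersion: float = 2.0
    zero_inflation: float = 0.2
    logfc_per_class: "np.ndarray | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise ValueError("n_locations must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.layout not in ("grid", "random"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.pattern not in ("stripes", "radial", "complex"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.n_signal_genes_per_class * self.n_classes > self.n_genes:
            raise ValueError(
                "n_signal_genes_per_class * n_classes exceeds n_genes"
            )
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd must be nonnegative")
        if self.logfc_per_class is None:
            self.logfc_per_class = np.log(np.linspace(2.0, 8.0, self.n_classes))
        self.logfc_per_class = np.asarray(self.logfc_per_class, dtype=float)
        if self.logfc_per_class.shape != (self.n_classes,):
            raise ValueError("logfc_per_class must have one entry per class")

    @property
    def class_names(self) -> np.ndarray:
        """Class labels "A", "B", ... (wraps to A1, B1, ... past 26)."""
        letters = string.ascii_uppercase
        names = [
            letters[i % 26] + ("" if i < 26 else str(i // 26))
            for i in range(self.n_classes)
        ]
        return np.array(names, dtype=object)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["logfc_per_class"] = [float(v) for v in self.logfc_per_class]
        return d


def generate_coordinates(layout: str, n: int, seed: int = 0) -> np.ndarray:
    """Generate ``n`` 2-D measurement locations.

    ``grid`` lays points on the most-square integer lattice with
    ``ceil(sqrt(n))`` columns and unit spacing, truncated to exactly ``n``
    points (row-major). ``random`` draws points uniformly on a square of side
    ``sqrt(n)`` so point density stays ~1 across sizes.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if layout == "grid":
        ncols = int(np.ceil(np.sqrt(n)))
        idx = np.arange(n)
        return np.column_stack((idx % ncols, idx // ncols)).astype(float)
    if layout == "random":
        rng = np.random.default_rng(seed)
        side = float(np.sqrt(n))
        return rng.uniform(0.0, side, size=(n, 2))
    raise ValueError(f"unknown layout {layout!r}")


def assign_domain_labels(
    coords: np.ndarray,
    pattern: str,
    n_classes: int = 6,
    seed: int = 0,
    class_names: "np.ndarray | None" = None,
) -> np.ndarray:
    """Assign each location to one of ``n_classes`` spatial domains.

    stripes
        Equal-width vertical bands of the x-range; a point's label depends
        only on its x coordinate.
    radial
        Equal-population concentric annuli around the coordinate centroid;
        a point's label depends only on its distance to the centroid
        (distance ties broken by row index).
    complex
        Nearest of ``n_classes * 3`` uniformly placed Voronoi seed points,
        each seed pre-assigned a class so every class owns >= 1 seed.

    Every class in the returned labelling is nonempty.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n_classes < 2:
        raise ValueError("n_classes must be at least 2")
    if np.unique(coords, axis=0).shape[0] < n_classes:
        raise ValueError(
            "infeasible layout: fewer distinct coordinates than classes"
        )
    if class_names is None:
        letters = string.ascii_uppercase
        class_names = np.array(
            [letters[i % 26] + ("" if i < 26 else str(i // 26))
             for i in range(n_classes)],
            dtype=object,
        )

    if pattern == "stripes":
        x = coords[:, 0]
        lo, hi = x.min(), x.max()
        width = (hi - lo) / n_classes
        idx = np.clip(((x - lo) / width).astype(int), 0, n_classes - 1)
    elif pattern == "radial":
        d = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
        order = np.argsort(d, kind="stable")
        idx = np.empty(n, dtype=int)
        idx[order] = (np.arange(n) * n_classes) // n
    elif pattern == "complex":
        rng = np.random.default_rng(seed)
        n_seeds = n_classes * _VORONOI_SEEDS_PER_CLASS
        lo, hi = coords.min(axis=0), coords.max(axis=0)
        seed_pts = rng.uniform(lo, hi, size=(n_seeds, 2))
        seed_class = np.tile(np.arange(n_classes), _VORONOI_SEEDS_PER_CLASS)
        _, nearest = cKDTree(seed_pts).query(coords, k=1)
        idx = seed_class[nearest]
        # repair pathologically empty classes by stealing the cell nearest
        # to one of the class's seeds
        for c in range(n_classes):
            if not np.any(idx == c):
                anchor = seed_pts[seed_class == c][0]
                idx[np.argmin(np.linalg.norm(coords - anchor, axis=1))] = c
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    if any(not np.any(idx == c) for c in range(n_classes)):
        raise ValueError("infeasible layout: a domain class came out empty")
    return class_names[idx]


def signal_gene_blocks(cfg: SimulationConfig) -> dict:
    """Map class name -> slice of that class's signal-gene columns."""
    s = cfg.n_signal_genes_per_class
    return {
        name: slice(c * s, (c + 1) * s)
        for c, name in enumerate(cfg.class_names)
    }


def simulate_counts(labels: np.ndarray, cfg: SimulationConfig) -> sp.csr_matrix:
    """Sample the zero-inflated NB count matrix for labelled locations.

    Per-gene baseline means are LogNormal(baseline_log_mean, baseline_log_sd);
    a cell of class ``c`` has its class's signal-gene means multiplied by
    ``exp(logfc_c)``. Counts are NB(mean, size=dispersion), then zeroed
    independently with probability ``zero_inflation``. Deterministic given
    ``cfg.seed`` (stream independent of chunking because the chunk size is a
    module constant).
    """
    labels = np.asarray(labels)
    names = cfg.class_names
    unknown = set(labels.tolist()) - set(names.tolist())
    if unknown:
        raise ValueError(f"unknown class label(s): {sorted(unknown)}")
    n, g = labels.shape[0], cfg.n_genes
    rng = np.random.default_rng(_child_seeds(cfg.seed, 3)[2])

    mu = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=g)
    blocks = signal_gene_blocks(cfg)
    # per-class mean vectors (class signal block scaled, rest baseline)
    class_mu = {}
    for c, name in enumerate(names):
        m = mu.copy()
        m[blocks[name]] *= np.exp(cfg.logfc_per_class[c])
        class_mu[name] = m
    label_to_row = {name: class_mu[name] for name in names}

    size = cfg.dispersion
    chunks = []
    for start in range(0, n, _CHUNK_ROWS):
        stop = min(start + _CHUNK_ROWS, n)
        means = np.vstack([label_to_row[l] for l in labels[start:stop]])
        p = size / (size + means)
        block = rng.negative_binomial(size, p).astype(np.int32)
        block_sp = sp.csr_matrix(block)
        if cfg.zero_inflation > 0 and block_sp.nnz:
            drop = rng.random(block_sp.nnz) < cfg.zero_inflation
            block_sp.data[drop] = 0
            block_sp.eliminate_zeros()
        chunks.append(block_sp)
    return sp.vstack(chunks).tocsr()


def make_dataset(cfg: SimulationConfig) -> STDataset:
    """Generate a full dataset (coordinates, domain labels, counts)."""
    s_coord, s_label, _ = _child_seeds(cfg.seed, 3)
    coords = generate_coordinates(cfg.layout, cfg.n_locations, seed=s_coord)
    labels = assign_domain_labels(
        coords, cfg.pattern, cfg.n_classes, seed=s_label,
        class_names=cfg.class_names,
    )
    counts = simulate_counts(labels, cfg)
    return STDataset(
        counts=counts, coords=coords, labels=labels, meta=cfg.to_dict()
    )


def make_rare_state_dataset(
    n_locations: int = 2000,
    n_genes: int = 600,
    rare_fraction: float = 0.01,
    seed: int = 0,
) -> STDataset:
    """Stripe dataset with a rare, transcriptomically distinct cell state.

    Five stripe domains (classes A-E, modest fold changes 2-4) plus a rare
    class F scattered uniformly over the tissue at ``rare_fraction`` of
    cells. F is given a broad, strong marker program — its own block of
    ``n_genes // 6`` signal genes at 8-fold — so that its singular direction
    rises above the noise floor of the count matrix and the state is
    actually detectable in a low-rank basis; a weak or narrow program would
    make the recovery question vacuous for every sketching design.
    """
    if not 0 < rare_fraction < 0.5:
        raise ValueError("rare_fraction must lie in (0, 0.5)")
    cfg = SimulationConfig(
        n_locations=n_locations,
        n_genes=n_genes,
        layout="random",
        pattern="stripes",
        n_classes=6,
        n_signal_genes_per_class=n_genes // 6,
        logfc_per_class=np.log([2.0, 2.5, 3.0, 3.5, 4.0, 8.0]),
        seed=seed,
    )
    s_coord, s_label, s_rare = _child_seeds(seed, 3)
    coords = generate_coordinates("random", n_locations, seed=s_coord)
    labels = assign_domain_labels(
        coords, "stripes", 6, seed=s_label, class_names=cfg.class_names
    )
    labels[labels == "F"] = "E"  # F exists only as the scattered rare state
    rng = np.random.default_rng(s_rare)
    n_rare = max(1, int(round(rare_fraction * n_locations)))
    labels[rng.choice(n_locations, size=n_rare, replace=False)] = "F"
    counts = simulate_counts(labels, cfg)
    meta = cfg.to_dict()
    meta["rare_fraction"] = rare_fraction
    return STDataset(counts=counts, coords=coords, labels=labels, meta=meta)
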