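# stsketch

Spatially aware sketching of spatial transcriptomics (ST) data.

Modern ST platforms (Visium HD, Xenium, MERFISH) profile 10⁵–10⁶ cells or
locations per section, so routine analysis increasingly starts by
*sketching* — selecting a small subset of cells that preserves the structure
of the full dataset. Designs developed for scRNA-seq optimize coverage of
the expression manifold only; on tissue they can over-sample
transcriptionally variable regions and under-sample homogeneous ones,
biasing every downstream spatial analysis. `stsketch` is for computational
biologists who want to subsample ST data *and know what the subsample costs
them*, in both expression space and physical space.

## What it implements

**Sketching designs** over a chosen representation (20-component PCA scores,
raw spatial coordinates, or spatially smoothed PCA):

* **uniform** — k indices without replacement, equal probability;
* **leverage score** — rows drawn with probability proportional to
  ℓᵢ = ‖Uᵢ·‖², the squared row norms of an orthonormal basis U of the
  normalized cell-by-gene matrix (the hat-matrix diagonal); computed exactly
  on a randomized-SVD basis or approximated by random projection + QR;
* **spatially smoothed leverage score** — the same scores taken from the
  smoothed basis Ū = W U, where W is a row-stochastic k-nearest-neighbor
  spatial weights matrix: leverage is blended across each cell's tissue
  neighborhood, coupling transcriptomic influence with spatial coverage;
* **minimax** (Hausdorff-coverage design) — grid-accelerated farthest-point
  coverage minimizing maxₓ minₛ d(x, s);
* **maximin** (spread design) — greedy farthest-first traversal maximizing
  the minimum pairwise distance within the sketch.

Each design is a scikit-learn style estimator (`UniformSketcher`,
`LeverageSketcher`, `MinimaxSketcher`, `MaximinSketcher`) with
`fit`/`transform`/`get_params`, selected row indices in `indices_`.

**Evaluation metrics** — directed partial Hausdorff distance
(q-quantile of nearest-sketch-neighbor distances, in expression and in
coordinate space), adjusted Rand index of sketch-derived clusters against
reference labels, PCA projection drift, kNN cell-type-composition MSE, and
an overall spatial score rank-summing the three spatial metrics.

**A synthetic ST generator** — Visium-like grids or Xenium-like random
coordinates; stripe, radial, or Voronoi-mosaic domain layouts; six domain
classes with class-specific log-fold changes on disjoint signal-gene
blocks; zero-inflated negative-binomial counts. Defaults produce the
100,000-location × 500-gene configurations the benchmark targets.

**A benchmark orchestrator** running methods × representations ×
fractions × replicates with shared preprocessing (QC at ≥100 counts and a
5×MAD library-size filter, log1p normalization, 20-component PCA).

## Worked example

```python
import stsketch as sts

cfg = sts.SimulationConfig(n_locations=5000, n_genes=500, layout="random",
                           pattern="stripes", seed=0)
ds = sts.make_dataset(cfg)

bench = sts.BenchmarkConfig(
    conditions=(("uniform", "counts"), ("leverage", "pca"),
                ("leverage_smoothed", "smoothed_pca"),
                ("minimax", "coords"), ("maximin", "pca")),
    fractions=(0.1,), replicates=3,
)
records, ranks = sts.run_benchmark(ds, bench)
cols = ["ari", "hausdorff_coord", "neighborhood_mse", "overall_spatial_score"]
print(ranks[cols].round(3).sort_values("overall_spatial_score"))
```

prints

```
                                    ari  hausdorff_coord  neighborhood_mse  overall_spatial_score
method            representation
leverage          pca             0.696            4.003             0.018                    8.0
leverage_smoothed smoothed_pca    0.773            4.389             0.018                    8.0
uniform           counts          0.689            4.067             0.017                    8.0
minimax           coords          0.673            2.779             0.018                    9.0
maximin           pca             0.660            3.952             0.018                   12.0
```

Read it as: smoothed leverage recovers the domain structure best
(ARI 0.773 — clustering a 10% sketch against the known stripe labels),
coordinate minimax leaves the smallest spatial holes (coordinate Hausdorff
2.78 distance units vs ~4 for the expression-space designs), and the
overall spatial score (sum of the three spatial-metric ranks, lower is
better) summarizes the trade-off. Values are exactly reproducible for a
given seed; the full table is in `records` (long form, one row per
condition × fraction × replicate × metric).

The same pipeline is scriptable from the shell:

```bash
stsketch simulate --layout random --pattern stripes --n-locations 5000 \
    --n-genes 500 --seed 0 --out sim/
stsketch sketch --dataset sim/ --method leverage-smoothed --rep smoothed \
    --fraction 0.1 --seed 1 --out sketch.csv
stsketch evaluate --dataset sim/ --sketch sketch.csv --out metrics.csv
stsketch benchmark --dataset sim/ --config bench.json --out bench/
```

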