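# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `stsketch`, in the package's own terms. It states nothing the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data model

A simulated dataset is a triple (coordinates, domain labels, counts).

**Geometry.** `grid` (Visium-like) lays n points on the most-square integer
lattice with ⌈√n⌉ columns, unit spacing, truncated row-major to exactly n
points. `random` (Xenium-like) draws n points uniformly on a square of side
√n, so point density is ≈ 1 per unit area at every n and neighborhood length
scales are comparable across sizes.

**Domain layouts.** `stripes`: n_classes equal-width vertical bands of the
x-range. `radial`: equal-population concentric annuli around the centroid
(rank-based, so classes are balanced by construction). `complex`: nearest of
n_classes × 3 uniformly placed Voronoi seeds, each seed pre-assigned a class
so every class owns at least one seed; this yields an irregular multi-domain
mosaic. Three seeds per class is a fixed constant: fewer gives overly
convex domains, many more fragments them below the spatial-smoothing length
scale.

**Expression.** Gene g has baseline mean μ_g ~ LogNormal(log 0.5, 1). Each
class owns a disjoint block of 25 signal genes (defaults; 6 × 25 of 500
genes), multiplied by exp(logfc_c) for cells of class c, with the six
default fold changes evenly spaced on [2, 8]. Counts are negative binomial
in the mean/size parameterization (variance μ + μ²/size, size = 2), then
zeroed independently with probability 0.2. Defaults were chosen for an
imaging-ST count regime (median library ≈ 200–400 over a 500-gene panel)
and are gated by a separability requirement: a 10,000-cell default dataset
must cluster back to its ground-truth domains at ARI ≥ 0.7 from a
20-component PCA (the acceptance suite checks exactly this). Measured
recovery across dataset draws at the default Leiden resolution of 1.0 is
0.62–0.89: most draws land at 0.70–0.85 with ~6 communities, while an
occasional draw is over-split into 8–10 communities and dips below 0.7.
Lowering the resolution merges those splits on full 10,000-cell data but
under-splits the ~1,000-cell sketches the benchmark clusters with the same
machinery (modularity resolution interacts with graph size), so the field's
standard default is kept and the variability stated here rather than hidden
by per-size retuning.

**What the generator does not emulate.** Gene–gene correlation beyond the
block structure, within-domain expression gradients, segmentation errors,
spatially varying capture efficiency, batch effects, and realistic marker
sparsity. Passing benchmarks here therefore demonstrates correct behavior of
the designs under a clean, separable, homogeneous-noise model — not
performance on real tissue, where the relative orderings of designs are
known to shift with the data's structure.

**Rare-state dataset.** `make_rare_state_dataset` builds the rare-state
recovery condition: five stripe domains with modest fold changes (2–4) plus
a 1% class scattered uniformly, distinct across a 100-gene block at 8-fold
in a 600-gene panel. The breadth/strength is a detectability requirement,
not a tuning knob: a low-rank basis can only carry a rare state whose
singular direction δ·√(n_rare cells) exceeds the matrix's noise floor
(≈ sd·(√n + √g) for i.i.d. noise). Under the standard defaults (25 signal
genes, modest fold change) a 1% class sits well below that floor — its
leverage is indistinguishable from the bulk's and *no* sampling design can
preferentially recover it — so the recovery experiment would be vacuous.
The experiment also runs on the unfiltered matrix: the MAD library-size
filter removes strongly expressing rare cells as outliers, which is itself
a caveat worth knowing when QC-ing data with rare high-expression states.

## Preprocessing

QC removes cells with total counts < 100, then cells whose total deviates
from the mean by more than 5 × the mean absolute deviation (MAD about the
mean, two-sided, computed on the cells passing the first rule). The MAD is
the *mean* absolute deviation, on raw totals; the low tail is already
handled by the count floor. Normalization is library-size scaling to 10,000
counts (the prevailing convention) followed by natural log1p; zeros map to
zeros. The embedding is a 20-component PCA solved exactly through the
gene–gene covariance eigendecomposition — deterministic, and exact rather
than randomized at panel widths of ≤ a few thousand genes; a seed parameter
is accepted and threaded through for interface stability. The leverage
basis U comes from a separate seeded randomized SVD of the normalized
(uncentered) matrix with 10 oversamples and 4 power iterations.

## Spatial weights and smoothing

W is row i supported on cell i's k = 15 nearest spatial neighbors plus
itself, uniform weights, rows normalized to sum 1 (Gaussian kernel with
σᵢ = distance to the k-th neighbor is available). kNN row-stochastic
averaging is the minimal construction consistent with "spatial weights
matrix"; both the neighborhood size and the kernel are exposed. Smoothing
is a single pass, Ū = W U, with no re-orthonormalization — the smoothed
basis is deliberately not an orthonormal basis, and its squared row norms
are used as sampling scores as-is. Smoothing is a convex averaging, so it
contracts per-column variance and raises spatial autocorrelation; both are
asserted in the test suite.

## Sketching designs

Sketch size is k = max(1, ⌊fraction · n⌋) everywhere (with a 1e-9 epsilon so
fractions constructed as k/n floor exactly). All designs are deterministic
given their seed; ties break toward the lowest index so small instances are
oracle-checkable.

**Weighted sampling without replacement** draws k indices with inclusion
proportional to score via exponential race keys (key_i = Exp(1)/score_i, k
smallest win), which realizes sequential renormalized
probability-proportional-to-size draws in O(n log n); the distributional
equivalence is exercised by Monte-Carlo goodness-of-fit tests against the
uniform special case and a binomial oracle.

**Minimax** binary-searches (30 iterations) a lattice cell width between 0
and the bounding-box diagonal for the smallest occupied-cell count ≥ k,
then samples k occupied cells and one uniform member per cell; if duplicate
points leave fewer occupied cells than k at any width, the sketch is
completed farthest-first. **Maximin** is the classic greedy farthest-first
traversal from a uniformly random start — a 2-approximation of the optimal
maximin design, verified exhaustively on instances up to n = 25, k = 5.
The random start (rather than, e.g., the max-norm point) gives the
replicate-to-replicate variability the benchmark's 10-seed protocol needs.

**Leverage representations.** `counts`: approximate scores on the
normalized cell-by-gene matrix (projection width rank + 10, pivoted QR with
rank truncation). `pca`: exact scores ‖Uᵢ·‖² on the randomized-SVD basis U.
`smoothed_pca`: raw squared row norms of Ū = W U — the spatially aware
variant. Scoring the singular basis (not centered PCA scores) makes the
identity-weights case coincide exactly with the plain variant, which the
tests assert.

## Evaluation metrics

Partial Hausdorff uses exact nearest-neighbor search (brute force above 3
dimensions, where kd-trees lose to BLAS) and the q = 0.99 quantile by
default; q is exposed since reasonable choices between 0.9 and 1 reorder
little but change scale. Clustering for ARI is a shared-nearest-neighbor
graph (k = 15, Jaccard weights) with seeded Leiden modularity optimization;
sketch-derived clusters are computed on the sketch's *own* 20-component PCA
of its normalized rows, not on sliced full-data scores. The reference is
ground-truth labels when present, otherwise a seeded full-data clustering
computed once. PCA projection drift sign-aligns the sketch-fitted
components to the full-data projections per column and reports the mean
Euclidean distance between the paired score vectors; no rotational
alignment is applied, because a rotation of the fitted axes *is* drift.
Consequence (documented limitation): with tied or near-tied eigenvalues the
fitted axes are arbitrary within an eigenspace and the metric conflates
that arbitrariness with drift; and even for data of exact rank d, a subset
rotates the within-subspace axes, so the metric is zero only for the full
sketch, not for every subspace-spanning subset. Neighborhood MSE compares
each sketched cell's k = 20 nearest-neighbor label proportions in the full
population against the sketched population (self excluded, shared category
set); it is bounded by 2. The overall spatial score ranks
replicate-averaged ARI (high = rank 1), coordinate Hausdorff and
neighborhood MSE (low = rank 1), average-ranks ties, and sums the three.

A measured property of the neighborhood MSE worth knowing: because it
averages over *sketched* locations, a sketch concentrated in a homogeneous
region is locally dense and scores *well* on this metric (≈ 0.009 vs
≈ 0.034 for uniform at fraction 0.1 on a 2,000-cell stripe dataset) while
its coordinate Hausdorff collapses (> 3× worse than uniform). The metric
quantifies local compositional fidelity at the sampled sites; spatial
coverage bias is caught by the coordinate Hausdorff term, which is why the
overall score sums both.

## Benchmark

Preprocessing, weights, bases and embeddings are computed once per dataset
and shared across the whole matrix; replicate r uses seed base_seed + r for
every stochastic stage, so a rerun is byte-identical. Invalid
method × representation pairs are rejected up front; uniform × coordinates
is always invalid (on any layout it is plain uniform sampling), and a
`skip_coords_on_grid` switch drops coordinate-representation conditions on
regular grids, where coordinate sketching adds little beyond uniform.

Measured design behavior on the default simulations (3,000–10,000 cells,
fraction 0.1, q = 0.99), from the acceptance suite and the numbers the
acceptance script recomputes: coordinate-space designs dominate coordinate
Hausdorff, with greedy maximin on coordinates the strongest (≈ 2.3 vs
≈ 2.9 for grid-accelerated minimax and ≈ 4.0 for uniform on a 2,500-point
grid) — systematically, not interchangeably with uniform; in expression
space the grid-accelerated minimax shows the worst robust Hausdorff of the
tested designs while greedy maximin is competitive; spatially smoothed
leverage attains the best replicate-averaged ARI on stripe layouts
(≈ 0.76 vs ≈ 0.69–0.73 for the alternatives) and leverage-score designs
recover a detectable 1% rare state in more sketch seeds than uniform
(≈ 85–90 vs ≈ 60 of 100). Orderings among near-tied designs vary with the
dataset seed; only the replicate-averaged effects listed here were stable
across the seeds tried.

## Problem sizes and numerical choices

Test and acceptance workloads use 2,000–10,000 cells (full-scale 100,000 ×
500 generation is exercised for the dimension checks); these sizes keep
every stochastic check a multi-seed Monte-Carlo while the effects measured
above are already stable. Nearest-neighbor searches are exact at these
sizes. Orthonormality is validated at 1e-8 (bases) and 1e-6 (leverage
input); row-stochasticity at 1e-8; degenerate inputs (duplicate
coordinates, all-identical points, zero-score rows, empty classes) have
defined behavior and tests. Seeds are plumbed as integers below 2³¹;
derived streams use `numpy` SeedSequence spawning so stages are independent
but reproducible.
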