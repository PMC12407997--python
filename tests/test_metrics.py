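import itertools

import numpy as np
import pandas as pd
import pytest

import stsketch as sts
from stsketch.sketchers import Sketch


def brute_force_directed_hausdorff(full, sketch, q=1.0):
    """Independent oracle: all-pairs distances, then the q-quantile."""
    D = np.linalg.norm(full[:, None, :] - sketch[None, :, :], axis=2)
    nn = D.min(axis=1)
    return nn.max() if q == 1.0 else np.quantile(nn, q)


def pair_counting_ari(a, b):
    """Independent oracle: ARI from explicit enumeration of item pairs."""
    n = len(a)
    same_a = same_b = same_both = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        same_a += sa
        same_b += sb
        same_both += sa and sb
    pairs = n * (n - 1) // 2
    expected = same_a * same_b / pairs
    max_index = (same_a + same_b) / 2
    if max_index == expected:
        return 1.0  # degenerate: both partitions all-singletons or all-one
    return (same_both - expected) / (max_index - expected)


class TestPartialHausdorff:
    def test_self_coverage_is_zero(self, rng):
        pts = rng.normal(size=(50, 3))
        for q in (0.5, 0.9, 1.0):
            assert sts.partial_hausdorff(pts, pts, q=q) == 0.0

    def test_line_example(self):
        full = np.array([[0.0], [1.0], [5.0]])
        sketch = np.array([[0.0]])
        assert sts.partial_hausdorff(full, sketch, q=1.0) == 5.0
        assert sts.partial_hausdorff(full, sketch, q=0.5) == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for n, m, d in [(120, 10, 2), (500, 40, 5), (80, 3, 20)]:
            full = rng.normal(size=(n, d))
            sketch = full[rng.choice(n, size=m, replace=False)]
            assert np.isclose(
                sts.partial_hausdorff(full, sketch, q=1.0),
                brute_force_directed_hausdorff(full, sketch),
                atol=1e-9,
            )

    def test_nested_sketch_monotonicity(self, rng):
        full = rng.normal(size=(200, 4))
        small = full[:10]
        large = full[:30]  # superset
        for q in (0.7, 1.0):
            assert (sts.partial_hausdorff(full, large, q=q)
                    <= sts.partial_hausdorff(full, small, q=q))

    def test_nondecreasing_in_q(self, rng):
        # a quantile of the NN-distance distribution grows with q
        full = rng.normal(size=(150, 3))
        sketch = full[:5]
        vals = [sts.partial_hausdorff(full, sketch, q=q)
                for q in (0.25, 0.5, 0.75, 0.95, 1.0)]
        assert np.all(np.diff(vals) >= 0)

    def test_empty_sketch_rejected(self, rng):
        with pytest.raises(ValueError):
            sts.partial_hausdorff(rng.normal(size=(5, 2)),
                                  np.empty((0, 2)))


class TestClusterForAri:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(size=(100, 5))
        b = rng.normal(size=(100, 5)) + 20.0  # 20 sigma separation
        pts = np.vstack((a, b))
        labels = sts.cluster_for_ari(pts, resolution=0.5, seed=0)
        truth = np.repeat([0, 1], 100)
        assert sts.adjusted_rand_index(labels, truth) == 1.0

    def test_deterministic(self, rng):
        pts = rng.normal(size=(120, 4))
        a = sts.cluster_for_ari(pts, seed=3)
        b = sts.cluster_for_ari(pts, seed=3)
        assert np.array_equal(a, b)

    def test_order_invariant_partition(self, rng):
        pts = np.vstack((rng.normal(size=(60, 3)),
                         rng.normal(size=(60, 3)) + 15.0))
        labels = sts.cluster_for_ari(pts, resolution=0.3, seed=0)
        perm = rng.permutation(120)
        labels_perm = sts.cluster_for_ari(pts[perm], resolution=0.3, seed=0)
        unpermuted = np.empty(120, dtype=int)
        unpermuted[perm] = labels_perm
        assert sts.adjusted_rand_index(labels, unpermuted) == 1.0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            sts.cluster_for_ari(np.zeros((1, 2)))


class TestAdjustedRandIndex:
    def test_perfect_and_relabeled_agreement(self):
        a = np.array([1, 1, 2, 2, 3])
        assert sts.adjusted_rand_index(a, a) == 1.0
        relabeled = np.array(["x", "x", "y", "y", "z"])
        assert sts.adjusted_rand_index(a, relabeled) == 1.0

    def test_crossed_partition_matches_pair_counting(self):
        a, b = [1, 1, 2, 2], [1, 2, 1, 2]
        assert np.isclose(sts.adjusted_rand_index(a, b),
                          pair_counting_ari(a, b))

    def test_symmetry_and_permutation_invariance(self, rng):
        a = rng.integers(0, 3, size=30)
        b = rng.integers(0, 4, size=30)
        assert np.isclose(sts.adjusted_rand_index(a, b),
                          sts.adjusted_rand_index(b, a))
        remap = {0: 9, 1: 7, 2: 5, 3: 3}
        b2 = np.array([remap[x] for x in b])
        assert np.isclose(sts.adjusted_rand_index(a, b),
                          sts.adjusted_rand_index(a, b2))

    def test_exhaustive_partitions_match_oracle(self):
        # all partition pairs of 5 items (Bell(5)^2 = 2704 comparisons)
        def partitions(n):
            labels = [[0]]
            for _ in range(n - 1):
                labels = [l + [v] for l in labels for v in range(max(l) + 2)]
            return labels

        parts = partitions(5)
        for a in parts:
            for b in parts:
                assert np.isclose(
                    sts.adjusted_rand_index(a, b), pair_counting_ari(a, b),
                    atol=1e-12,
                ), (a, b)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sts.adjusted_rand_index([1, 2], [1, 2, 3])


class TestPcaProjectionDifference:
    def test_full_sketch_is_zero(self, rng):
        X = rng.normal(size=(60, 8)) * np.linspace(4, 0.5, 8)
        _, loadings, center = sts.pca_embedding(X, d=3, seed=0)
        assert sts.pca_projection_difference(loadings, center, X, d=3) < 1e-6

    def test_exact_rank_subspace_recovered(self, rng):
        # data of exact rank d: a sketch spanning the subspace recovers the
        # same principal subspace, so reconstructions from both fitted bases
        # coincide (the score-space drift itself is pure within-subspace
        # rotation and need not vanish)
        from sklearn.decomposition import PCA

        B = rng.normal(size=(3, 10))
        X = rng.normal(size=(80, 3)) @ B
        _, loadings, center = sts.pca_embedding(X, d=3, seed=0)
        rows = X[rng.choice(80, size=30, replace=False)]
        full_recon = (rows - center) @ loadings @ loadings.T + center
        pca = PCA(n_components=3).fit(rows)
        sketch_recon = pca.inverse_transform(pca.transform(rows))
        assert np.allclose(full_recon, rows, atol=1e-6)
        assert np.allclose(sketch_recon, rows, atol=1e-6)
        # and the score-space drift is finite and well-defined
        assert np.isfinite(
            sts.pca_projection_difference(loadings, center, rows, d=3)
        )

    def test_larger_sketches_drift_less(self, rng):
        X = rng.normal(size=(400, 10))
        _, loadings, center = sts.pca_embedding(X, d=4, seed=0)
        vals = {frac: [] for frac in (0.05, 0.5)}
        for s in range(20):
            r = np.random.default_rng(s)
            for frac in vals:
                rows = X[r.choice(400, size=int(400 * frac), replace=False)]
                vals[frac].append(
                    sts.pca_projection_difference(loadings, center, rows, d=4)
                )
        assert np.mean(vals[0.5]) <= np.mean(vals[0.05])

    def test_insufficient_rank(self, rng):
        X = rng.normal(size=(10, 5))
        _, loadings, center = sts.pca_embedding(X, d=4, seed=0)
        with pytest.raises(ValueError):
            sts.pca_projection_difference(loadings, center, X[:4], d=4)


class TestNeighborhoodComposition:
    def test_single_label_one_hot(self, rng):
        coords = rng.uniform(size=(30, 2))
        labels = np.array(["A"] * 30)
        props, cats = sts.neighborhood_composition(
            coords, labels, np.arange(30), k=5
        )
        assert np.all(props == 1.0) and list(cats) == ["A"]

    def test_rows_sum_to_one(self, rng):
        coords = rng.uniform(size=(100, 2))
        labels = rng.choice(["A", "B", "C"], size=100)
        props, _ = sts.neighborhood_composition(
            coords, labels, np.arange(0, 100, 7), k=9
        )
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)

    def test_hand_enumerated_example(self):
        # six points on a line at x = 0..5, labels A A B B C C, k = 3;
        # e.g. the point at 0 has neighbours {1,2,3} -> (A, B, B)
        coords = np.column_stack((np.arange(6.0), np.zeros(6)))
        labels = np.array(["A", "A", "B", "B", "C", "C"])
        props, cats = sts.neighborhood_composition(
            coords, labels, np.array([0, 2, 5]), k=3
        )
        assert list(cats) == ["A", "B", "C"]
        assert np.allclose(props[0], [1 / 3, 2 / 3, 0])  # nbrs 1,2,3 -> A,B,B
        # point 2: nbrs 1,3 at d=1; tie at d=2 between 0 and 4 broken to the
        # lower index -> nbrs 0,1,3 -> A,A,B
        assert np.allclose(props[1], [2 / 3, 1 / 3, 0])
        assert np.allclose(props[2], [0, 2 / 3, 1 / 3])  # nbrs 2,3,4 -> B,B,C


class TestNeighborhoodMse:
    def make_labelled(self, rng, n=300):
        coords = rng.uniform(0, 10, size=(n, 2))
        labels = np.where(coords[:, 0] < 5, "L", "R")
        counts = rng.integers(0, 3, size=(n, 5))
        return sts.STDataset(counts=counts, coords=coords, labels=labels)

    def test_full_sketch_zero(self, rng):
        ds = self.make_labelled(rng)
        sk = Sketch(indices=np.arange(ds.n), method="uniform",
                    representation="counts", fraction=1.0, seed=0)
        assert sts.neighborhood_mse(ds, sk, k=10) == 0.0

    def test_single_label_zero(self, rng):
        ds = self.make_labelled(rng)
        ds = sts.STDataset(counts=np.asarray(ds.counts), coords=ds.coords,
                           labels=np.array(["A"] * ds.n))
        sk = Sketch(indices=np.arange(0, ds.n, 3), method="uniform",
                    representation="counts", fraction=1 / 3, seed=0)
        assert sts.neighborhood_mse(ds, sk, k=10) == 0.0

    def test_bounded_above_by_two(self, rng):
        ds = self.make_labelled(rng)
        for s in range(5):
            sk = sts.uniform_sketch(ds.n, 0.2, seed=s)
            assert 0.0 <= sts.neighborhood_mse(ds, sk, k=10) <= 2.0

    def test_concentration_trades_local_fidelity_for_coverage(self, small_dataset):
        # a sketch crammed into one homogeneous stripe is locally dense, so
        # its own neighborhoods look faithful (low MSE at sketched sites) —
        # the over-sampling bias surfaces as a collapse of tissue coverage,
        # i.e. a far larger coordinate Hausdorff distance than uniform's
        ds = small_dataset
        k = sts.sketch_size(ds.n, 0.1)
        one_stripe = np.flatnonzero(ds.labels == "A")
        u_mse, b_mse, u_haus, b_haus = [], [], [], []
        for s in range(20):
            uni = sts.uniform_sketch(ds.n, 0.1, seed=s)
            u_mse.append(sts.neighborhood_mse(ds, uni, k=15))
            u_haus.append(sts.partial_hausdorff(
                ds.coords, ds.coords[uni.indices], q=0.99))
            rng_s = np.random.default_rng(s)
            picked = rng_s.choice(one_stripe, size=k, replace=False)
            biased = Sketch(indices=picked, method="uniform",
                            representation="counts", fraction=0.1, seed=s)
            b_mse.append(sts.neighborhood_mse(ds, biased, k=15))
            b_haus.append(sts.partial_hausdorff(
                ds.coords, ds.coords[picked], q=0.99))
        assert np.mean(b_mse) < np.mean(u_mse)
        assert np.mean(b_haus) > 3 * np.mean(u_haus)

    def test_small_sketch_rejected(self, rng):
        ds = self.make_labelled(rng)
        sk = Sketch(indices=np.arange(5), method="uniform",
                    representation="counts", fraction=5 / ds.n, seed=0)
        with pytest.raises(ValueError):
            sts.neighborhood_mse(ds, sk, k=10)


def record(method, rep, metric, value, fraction=0.1, replicate=0):
    return {"method": method, "representation": rep, "fraction": fraction,
            "replicate": replicate, "metric": metric, "value": value}


class TestRankSumScore:
    def test_single_condition_scores_three(self):
        rows = [record("uniform", "counts", m, v) for m, v in
                [("ari", 0.8), ("hausdorff_coord", 1.0),
                 ("neighborhood_mse", 0.1), ("hausdorff_expr", 2.0),
                 ("pca_diff", 0.5)]]
        table = sts.rank_sum_score(pd.DataFrame(rows))
        assert table["overall_spatial_score"].iloc[0] == 3.0

    def test_dominating_condition(self):
        rows = []
        for m, good, bad in [("ari", 0.9, 0.2), ("hausdorff_coord", 1.0, 5.0),
                             ("neighborhood_mse", 0.01, 0.5),
                             ("hausdorff_expr", 1.0, 2.0), ("pca_diff", 0.1, 0.9)]:
            rows.append(record("leverage", "pca", m, good))
            rows.append(record("maximin", "pca", m, bad))
        table = sts.rank_sum_score(pd.DataFrame(rows))
        assert table.loc[("leverage", "pca"), "overall_spatial_score"] == 3.0
        assert table.loc[("maximin", "pca"), "overall_spatial_score"] == 6.0

    def test_tie_averaging_matches_hand_computation(self):
        # three conditions; two tie on ARI -> ranks 1.5 each, third gets 3
        rows = []
        for cond, ari, haus, mse in [("a", 0.9, 1.0, 0.1),
                                     ("b", 0.9, 2.0, 0.2),
                                     ("c", 0.5, 3.0, 0.3)]:
            for m, v in [("ari", ari), ("hausdorff_coord", haus),
                         ("neighborhood_mse", mse),
                         ("hausdorff_expr", 1.0), ("pca_diff", 1.0)]:
                rows.append(record(cond, "pca", m, v))
        table = sts.rank_sum_score(pd.DataFrame(rows))
        assert table.loc[("a", "pca"), "rank_ari"] == 1.5
        assert table.loc[("b", "pca"), "rank_ari"] == 1.5
        assert table.loc[("a", "pca"), "overall_spatial_score"] == 1.5 + 1 + 1
        assert table.loc[("b", "pca"), "overall_spatial_score"] == 1.5 + 2 + 2
        assert table.loc[("c", "pca"), "overall_spatial_score"] == 3 + 3 + 3

    def test_totals_without_ties(self):
        rng = np.random.default_rng(0)
        conds = ["a", "b", "c", "d"]
        rows = []
        for cond in conds:
            for m in ("ari", "hausdorff_coord", "neighborhood_mse",
                      "hausdorff_expr", "pca_diff"):
                rows.append(record(cond, "pca", m, float(rng.uniform())))
        table = sts.rank_sum_score(pd.DataFrame(rows))
        m = len(conds)
        assert table["overall_spatial_score"].sum() == 3 * m * (m + 1) / 2

    def test_replicates_averaged_before_ranking(self):
        rows = []
        for rep_id, v in [(0, 0.2), (1, 0.8)]:  # mean ARI 0.5
            rows.append(record("a", "pca", "ari", v, replicate=rep_id))
        for m in ("hausdorff_coord", "neighborhood_mse", "hausdorff_expr",
                  "pca_diff"):
            rows.append(record("a", "pca", m, 1.0))
        table = sts.rank_sum_score(pd.DataFrame(rows))
        assert table.loc[("a", "pca"), "ari"] == 0.5

    def test_missing_metric_rejected(self):
        rows = [record("a", "pca", "ari", 0.5)]
        with pytest.raises(ValueError, match="missing"):
            sts.rank_sum_score(pd.DataFrame(rows))
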