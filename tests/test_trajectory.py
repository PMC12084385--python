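"""Lineage MST, pseudotime projection, association test, patterns."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lumipath import trajectory as traj

from conftest import toy_adata


class TestInferLineages:
    def test_two_clusters_single_lineage(self):
        X = np.vstack([np.zeros((10, 3)), np.ones((10, 3)) * 5])
        labels = ["a"] * 10 + ["b"] * 10
        res = traj.infer_lineages(X, labels, origin="a")
        assert res.lineages == [["a", "b"]]

    def test_three_collinear_clusters_single_path(self):
        X = np.vstack([np.full((5, 2), v) for v in (0.0, 5.0, 10.0)])
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = traj.infer_lineages(X, labels, origin="a")
        assert res.lineages == [["a", "b", "c"]]

    def test_y_shaped_toy_matches_exhaustive_spanning_tree_oracle(self):
        centers = {"o": (0, 0), "m": (5, 0), "l1": (8, 3), "l2": (8, -3),
                   "far": (14, 3)}
        rng = np.random.default_rng(0)
        X, labels = [], []
        for name, c in centers.items():
            X.append(rng.normal(c, 0.05, size=(6, 2)))
            labels += [name] * 6
        X = np.vstack(X)
        res = traj.infer_lineages(X, labels, origin="o")
        # exhaustive minimum spanning tree over all 4-edge subsets
        cents = {name: X[np.array(labels) == name].mean(axis=0)
                 for name in centers}
        nodes = sorted(centers)
        edges = list(itertools.combinations(nodes, 2))
        best, best_w = None, np.inf
        for subset in itertools.combinations(edges, 4):
            adj = {n: set() for n in nodes}
            for a, b in subset:
                adj[a].add(b)
                adj[b].add(a)
            seen = {nodes[0]}
            stack = [nodes[0]]
            while stack:
                for nb in adj[stack.pop()]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            if len(seen) < len(nodes):
                continue
            w = sum(np.linalg.norm(cents[a] - cents[b]) for a, b in subset)
            if w < best_w:
                best, best_w = subset, w
        assert sorted(res.mst_edges) == sorted(tuple(sorted(e)) for e in best)
        assert res.lineages == [["o", "m", "l1", "far"], ["o", "m", "l2"]]

    def test_missing_origin_errors(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="origin"):
            traj.infer_lineages(X, ["a"] * 4, origin="zz")


class TestPseudotime:
    def test_straight_segment_matches_projection_oracle(self):
        # cells on a straight line; pseudotime = clamped signed distance
        # along the centroid-to-centroid segment (closed-form oracle)
        rng = np.random.default_rng(4)
        line = np.linspace(0, 1, 11)[:, None] * np.array([[3.0, 4.0]])
        labels = ["a"] * 6 + ["b"] * 5
        pt, w, path = traj.compute_pseudotime(line, labels, ["a", "b"],
                                              refine_iterations=0)
        ca, cb = line[:6].mean(axis=0), line[6:].mean(axis=0)
        u = (cb - ca) / np.linalg.norm(cb - ca)
        L = np.linalg.norm(cb - ca)
        expected = np.clip((line - ca) @ u, 0.0, L)
        np.testing.assert_allclose(pt.to_numpy(), expected, atol=1e-10)
        assert np.all(w == 1.0)

    def test_origin_centroid_has_minimal_pseudotime(self):
        rng = np.random.default_rng(0)
        a = rng.normal((0, 0), 0.3, size=(20, 2))
        b = rng.normal((5, 0), 0.3, size=(20, 2))
        X = np.vstack([a, b, [a.mean(axis=0)], [b.mean(axis=0)]])
        labels = ["a"] * 20 + ["b"] * 20 + ["a", "b"]
        pt, w, _ = traj.compute_pseudotime(X, labels, ["a", "b"],
                                           refine_iterations=0)
        assert pt.iloc[-2] == pytest.approx(0.0, abs=1e-9)
        assert pt.iloc[-1] == pytest.approx(pt.max(), rel=1e-6)

    def test_off_lineage_cells_get_zero_weight(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 5,
                       np.full((5, 2), (0.0, 9.0))])
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        pt, w, _ = traj.compute_pseudotime(X, labels, ["a", "b"],
                                           refine_iterations=0)
        assert np.all(w.to_numpy()[10:] == 0.0)
        assert pt.iloc[10:].isna().all()


class TestAssociationTest:
    def _design(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, 10, size=n), rng

    def test_constant_gene_null(self):
        x, rng = self._design()
        Y = pd.DataFrame({"flat": np.full(len(x), 3.0),
                          "noise": rng.normal(size=len(x))})
        res = traj.association_test(Y, x, n_knots=6)
        tab = res.table.set_index("gene")
        assert tab.loc["flat", "wald_stat"] == pytest.approx(0.0, abs=1e-8)
        assert tab.loc["flat", "p_value"] == pytest.approx(1.0)

    def test_strong_linear_gene_detected(self):
        x, rng = self._design()
        Y = pd.DataFrame({"lin": 2.0 * x + rng.normal(0, 0.1, len(x))})
        res = traj.association_test(Y, x, n_knots=6)
        assert res.table["p_value"].iloc[0] < 1e-6

    def test_adjusted_p_dominates_raw(self):
        x, rng = self._design()
        Y = pd.DataFrame(rng.normal(size=(len(x), 30)))
        res = traj.association_test(Y, x, n_knots=6)
        assert (res.table["adj_p"] >= res.table["p_value"] - 1e-15).all()

    def test_degenerate_pseudotime_errors(self):
        Y = pd.DataFrame(np.random.default_rng(0).normal(size=(40, 3)))
        with pytest.raises(Exception, match="degenerate"):
            traj.association_test(Y, np.full(40, 2.0), n_knots=6)

    def test_too_few_cells_errors(self):
        Y = pd.DataFrame(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="fewer than 30"):
            traj.association_test(Y, np.linspace(0, 1, 10))


class TestFilterTrajectoryGenes:
    def test_inclusive_boundaries(self):
        X = np.zeros((25, 3), dtype=int)
        X[:20, 0] = 1    # exactly 20 cells with count >= 1 -> kept
        X[:19, 1] = 4    # 19 cells -> removed
        X[:, 2] = 2
        counts = pd.DataFrame(X, columns=["a", "b", "c"])
        assert traj.filter_trajectory_genes(counts) == ["a", "c"]

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(0.8, size=(60, 30))
        counts = pd.DataFrame(X, columns=[f"g{j}" for j in range(30)])
        kept = traj.filter_trajectory_genes(counts, min_count=2, min_cells=5)
        expected = [f"g{j}" for j in range(30)
                    if sum(X[i, j] >= 2 for i in range(60)) >= 5]
        assert kept == expected


class TestSmoothing:
    def test_window_of_all_cells_gives_global_means(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        pt = np.arange(8.0)
        sm, bins = traj.smooth_and_annotate(expr, pt, ["x"] * 8, window=8)
        assert sm.shape == (3, 1)
        np.testing.assert_allclose(sm.iloc[:, 0].to_numpy(),
                                   expr.mean(axis=0).to_numpy())
        assert bins == ["x"]

    def test_ten_cell_toy_matches_hand_rolling_means(self):
        expr = pd.DataFrame({"g": np.arange(10.0)})
        pt = np.arange(10.0)[::-1]  # reversed order: cells resorted first
        sm, _ = traj.smooth_and_annotate(expr, pt, ["x"] * 10, window=3)
        vals = np.arange(10.0)[::-1]  # expression ordered by pseudotime
        expected = [vals[i:i + 3].mean() for i in range(8)]
        np.testing.assert_allclose(sm.loc["g"].to_numpy(), expected)

    def test_constant_gene_smooths_constant(self):
        expr = pd.DataFrame({"g": np.full(10, 2.0)})
        sm, _ = traj.smooth_and_annotate(expr, np.arange(10.0), ["x"] * 10,
                                         window=4)
        np.testing.assert_array_equal(sm.loc["g"].to_numpy(), 2.0)

    def test_modal_annotation_tie_goes_to_earliest_cell(self):
        expr = pd.DataFrame({"g": np.zeros(4)})
        pt = np.arange(4.0)
        labels = ["b", "a", "b", "a"]
        _, bins = traj.smooth_and_annotate(expr, pt, labels, window=4)
        assert bins == ["b"]

    def test_window_bounds_enforced(self):
        expr = pd.DataFrame({"g": np.zeros(5)})
        with pytest.raises(ValueError):
            traj.smooth_and_annotate(expr, np.arange(5.0), ["x"] * 5, window=1)
        with pytest.raises(ValueError):
            traj.smooth_and_annotate(expr, np.arange(5.0), ["x"] * 5, window=6)


def average_linkage_oracle(profiles):
    """Naive O(n^3) agglomeration; returns sorted merge heights."""
    clusters = {i: [i] for i in range(len(profiles))}
    D = {}
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            D[(i, j)] = np.linalg.norm(profiles[i] - profiles[j])
    heights = []
    next_id = len(profiles)
    while len(clusters) > 1:
        (a, b), h = min(
            (((a, b), np.mean([D[tuple(sorted((i, j)))]
                               for i in clusters[a] for j in clusters[b]]))
             for a, b in itertools.combinations(sorted(clusters), 2)),
            key=lambda kv: kv[1])
        heights.append(h)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return sorted(heights)


class TestPatternGroups:
    def test_merge_heights_match_naive_oracle_on_12_profiles(self):
        rng = np.random.default_rng(0)
        profiles = rng.normal(size=(12, 9))
        sm = pd.DataFrame(profiles, index=[f"g{i}" for i in range(12)])
        res = traj.pattern_groups(sm, k=3)
        Z = profiles - profiles.mean(axis=1, keepdims=True)
        Z = Z / Z.std(axis=1, keepdims=True)
        expected = average_linkage_oracle(list(Z))
        np.testing.assert_allclose(sorted(res.linkage[:, 2]), expected,
                                   atol=1e-10)

    def test_duplicated_genes_always_co_assigned(self):
        rng = np.random.default_rng(1)
        profiles = rng.normal(size=(10, 12))
        profiles[7] = profiles[2]
        sm = pd.DataFrame(profiles, index=[f"g{i}" for i in range(10)])
        res = traj.pattern_groups(sm, k=3)
        assert res.groups["g2"] == res.groups["g7"]

    def test_three_archetypes_named_correctly(self):
        u = np.linspace(0, 1, 30)
        down = 1.0 / (1.0 + np.exp(14 * (u - 0.5)))
        up = 1.0 - down
        bump = np.exp(-((u - 0.5) / 0.15) ** 2)
        rng = np.random.default_rng(2)
        rows, names = [], []
        for i in range(5):
            rows += [down + rng.normal(0, 0.02, 30),
                     up + rng.normal(0, 0.02, 30),
                     bump + rng.normal(0, 0.02, 30)]
            names += [f"d{i}", f"u{i}", f"b{i}"]
        sm = pd.DataFrame(rows, index=names)
        res = traj.pattern_groups(sm, k=3)
        assert set(res.groups[[f"d{i}" for i in range(5)]]) == {"bas"}
        assert set(res.groups[[f"u{i}" for i in range(5)]]) == {"lum"}
        assert set(res.groups[[f"b{i}" for i in range(5)]]) == {"int"}

    def test_k_larger_than_gene_count_errors(self):
        sm = pd.DataFrame(np.zeros((2, 5)))
        with pytest.raises(ValueError):
            traj.pattern_groups(sm, k=3)
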