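"""Marker AUC, module scores, robust fit, adjusted proportions, cell cycle."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lumipath import signatures as sig

from conftest import toy_norm


def auc_by_pair_enumeration(x_in, x_out):
    """Brute-force concordant-pair AUC (ties count one half)."""
    wins = sum(1.0 if a > b else (0.5 if a == b else 0.0)
               for a, b in itertools.product(x_in, x_out))
    return wins / (len(x_in) * len(x_out))


class TestFindMarkers:
    def _toy(self, values):
        return toy_norm(np.asarray(values, dtype=float))

    def test_perfect_separation_auc_one(self):
        vals = np.array([[5.0], [6.0], [7.0], [1.0], [2.0], [0.5]])
        norm = self._toy(vals)
        labels = ["in"] * 3 + ["out"] * 3
        table = sig.find_markers(norm, labels, target="in", min_pct=0.0)
        assert table["auc"].iloc[0] == 1.0

    def test_identical_distribution_auc_half(self):
        vals = np.array([[3.0], [4.0], [3.0], [4.0]])
        norm = self._toy(vals)
        table = sig.find_markers(norm, ["a", "a", "b", "b"], target="a",
                                 min_pct=0.0, only_pos=False)
        assert table["auc"].iloc[0] == 0.5

    def test_matches_pairwise_enumeration_on_8_cell_toy(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 6, size=(8, 5)).astype(float)
        norm = self._toy(vals)
        labels = ["in"] * 3 + ["out"] * 5
        table = sig.find_markers(norm, labels, target="in", min_pct=0.0,
                                 only_pos=False).set_index("gene")
        for j, g in enumerate(norm.var_names):
            expected = auc_by_pair_enumeration(vals[:3, j], vals[3:, j])
            assert table.loc[g, "auc"] == pytest.approx(expected)

    def test_min_pct_filter_and_positivity(self):
        vals = np.array([[0.0, 5.0], [0.0, 6.0], [2.0, 0.1], [2.5, 0.2]])
        norm = self._toy(vals)
        table = sig.find_markers(norm, ["a", "a", "b", "b"], target="a",
                                 min_pct=0.4, only_pos=True)
        # g0 never expressed in target, g1 passes both filters
        assert list(table["gene"]) == ["g1"]

    def test_empty_group_errors(self):
        norm = self._toy(np.ones((3, 2)))
        with pytest.raises(ValueError):
            sig.find_markers(norm, ["a", "a", "a"], target="a")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.lognormal(0.0, 1.0, size=(10, 3))
        labels = ["in"] * 4 + ["out"] * 6
        a = sig.find_markers(toy_norm(vals), labels, target="in",
                             min_pct=0.0, only_pos=False).set_index("gene")
        b = sig.find_markers(toy_norm(np.log1p(vals) * 2.0 + 3.0), labels,
                             target="in", min_pct=0.0,
                             only_pos=False).set_index("gene")
        np.testing.assert_allclose(a["auc"].sort_index(),
                                   b["auc"].sort_index(), atol=1e-12)


def module_score_oracle(X, gene_names, gene_set, n_bins, n_ctrl, seed):
    """Independent straight-line reimplementation of the bin-matched score."""
    avg = X.mean(axis=0)
    n_genes = X.shape[1]
    order = np.lexsort((np.arange(n_genes), avg))
    bins = np.empty(n_genes, dtype=int)
    bins[order] = (np.arange(n_genes) * n_bins) // n_genes
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(gene_names)}
    ctrl = set()
    for g in gene_set:
        pool = np.flatnonzero(bins == bins[idx[g]])
        ctrl.update(rng.choice(pool, size=min(n_ctrl, len(pool)),
                               replace=False).tolist())
    set_cols = [idx[g] for g in gene_set]
    return X[:, set_cols].mean(axis=1) - X[:, sorted(ctrl)].mean(axis=1)


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        norm = toy_norm(np.full((6, 30), 2.5))
        s = sig.module_score(norm, ["g0", "g1"], n_bins=3, n_ctrl=5, seed=0)
        np.testing.assert_array_equal(s.to_numpy(), 0.0)

    def test_whole_transcriptome_set_scores_near_zero(self):
        rng = np.random.default_rng(0)
        norm = toy_norm(rng.gamma(2.0, 1.0, size=(20, 60)))
        s = sig.module_score(norm, list(norm.var_names), n_bins=6,
                             n_ctrl=60, seed=0)
        assert np.abs(s).max() < 1e-9  # controls cover every bin completely

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.gamma(2.0, 1.0, size=(15, 50))
        norm = toy_norm(X)
        genes = ["g3", "g10", "g44", "g7"]
        s = sig.module_score(norm, genes, n_bins=2, n_ctrl=5, seed=42)
        expected = module_score_oracle(X, list(norm.var_names), genes,
                                       n_bins=2, n_ctrl=5, seed=42)
        np.testing.assert_allclose(s.to_numpy(), expected, atol=1e-12)

    def test_random_set_mean_zero_over_seeds(self, norm):
        rng = np.random.default_rng(99)
        means = []
        for _ in range(50):
            genes = rng.choice(norm.var_names, size=30, replace=False)
            s = sig.module_score(norm, list(genes), seed=int(rng.integers(1e6)))
            means.append(s.mean())
        ci = 3.0 * np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means)) < max(ci, 0.02)

    def test_missing_genes_dropped_with_warning(self):
        norm = toy_norm(np.random.default_rng(2).gamma(2, 1, size=(8, 40)))
        with pytest.warns(UserWarning, match="absent"):
            sig.module_score(norm, ["g1", "nope"], n_bins=4, n_ctrl=5, seed=0)

    def test_combined_luminal_is_union_score(self):
        rng = np.random.default_rng(3)
        norm = toy_norm(rng.gamma(2, 1, size=(10, 40)))
        a, b = ["g1", "g2"], ["g2", "g30"]
        combined = sig.combined_luminal_score(norm, a, b, n_bins=4,
                                             n_ctrl=5, seed=7)
        union = sig.module_score(norm, sorted(set(a) | set(b)), n_bins=4,
                                 n_ctrl=5, seed=7)
        np.testing.assert_allclose(combined.to_numpy(), union.to_numpy())

    def test_combined_with_one_empty_set_warns(self):
        rng = np.random.default_rng(4)
        norm = toy_norm(rng.gamma(2, 1, size=(10, 40)))
        with pytest.warns(UserWarning, match="empty"):
            s = sig.combined_luminal_score(norm, ["g1", "g2"], ["absent"],
                                          n_bins=4, n_ctrl=5, seed=7)
        only_a = sig.module_score(norm, ["g1", "g2"], n_bins=4, n_ctrl=5,
                                  seed=7)
        np.testing.assert_allclose(s.to_numpy(), only_a.to_numpy())


class TestRobustLinearFit:
    def test_exact_line_recovered_with_unit_weights(self):
        x = np.arange(10.0)
        fit = sig.robust_linear_fit(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert np.all(fit.weights == 1.0)

    def test_gross_outlier_downweighted_below_inliers(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 20)
        y = 3.0 * x + rng.normal(0, 0.05, 20)
        y[7] += 5.0
        fit = sig.robust_linear_fit(x, y)
        inlier_w = np.delete(fit.weights, 7)
        assert fit.weights[7] < inlier_w.min()

    def test_matches_statsmodels_rlm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = rng.uniform(0, 10, 40)
        y = 1.5 * x - 2.0 + rng.standard_t(3, size=40)
        fit = sig.robust_linear_fit(x, y)
        ref = sm.RLM(y, sm.add_constant(x),
                     M=sm.robust.norms.HuberT(t=1.345)).fit(
                         scale_est="mad", conv="coefs", tol=1e-10)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-4)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-4)

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            sig.robust_linear_fit(np.ones(5), np.arange(5.0))


class TestAdjustedProportion:
    def _toy(self, n_cells=12, n_markers=6, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.gamma(2.0, 1.0, size=(n_cells, n_markers + 4))
        return toy_norm(X), [f"g{j}" for j in range(n_markers)]

    def test_cell_above_every_threshold_scores_one(self):
        norm, markers = self._toy()
        X = norm.X.copy()
        X[0, :6] = X[:, :6].max(axis=0) + 1.0
        norm.X = X
        raw, _, _ = sig.adjusted_proportion_score(
            norm, markers, complexity=np.arange(norm.n_obs))
        assert raw.iloc[0] == 1.0

    def test_cell_exactly_at_thresholds_scores_zero(self):
        # strict inequality: sitting on every median counts as not expressed
        vals = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 5))
        vals = np.vstack([vals, np.full((1, 5), 2.0)])  # cell at the median
        norm = toy_norm(vals)
        raw, _, _ = sig.adjusted_proportion_score(
            norm, list(norm.var_names), complexity=np.arange(4))
        assert raw.iloc[3] == 0.0

    def test_huber_weighted_residual_mean_zero(self):
        rng = np.random.default_rng(5)
        norm, markers = self._toy(n_cells=40, seed=5)
        complexity = rng.integers(500, 3000, size=40)
        _, _, fit = sig.adjusted_proportion_score(norm, markers,
                                                  complexity=complexity)
        assert abs(np.sum(fit.weights * fit.residuals)) < 1e-8

    def test_missing_markers_warn_and_shrink_denominator(self):
        norm, markers = self._toy()
        with pytest.warns(UserWarning, match="absent"):
            raw, _, _ = sig.adjusted_proportion_score(
                norm, markers + ["ghost"], complexity=np.arange(norm.n_obs))
        assert raw.max() <= 1.0


class TestCellCycleScores:
    def test_phase_rule(self):
        # 3 cell groups: S-high, G2M-high, both-low; one expression bin so
        # the control set is the whole transcriptome
        X = np.full((9, 40), 1.0)
        X[:3, :5] = 4.0      # S genes high
        X[3:6, 5:10] = 4.0   # G2M genes high
        X[6:9, :10] = 0.5    # cycle genes below baseline -> G1
        norm = toy_norm(X)
        s_genes = [f"g{j}" for j in range(5)]
        g2m_genes = [f"g{j}" for j in range(5, 10)]
        out = sig.cell_cycle_scores(norm, s_genes, g2m_genes, seed=0,
                                    n_bins=1, n_ctrl=40)
        assert (out["phase"][:3] == "S").all()
        assert (out["phase"][3:6] == "G2M").all()
        assert (out["phase"][6:] == "G1").all()

    def test_cycling_cells_called_s_or_g2m_more_often(self, norm):
        s_genes = list(norm.var_names[norm.var["cc_class"] == "S"])
        g2m_genes = list(norm.var_names[norm.var["cc_class"] == "G2M"])
        out = sig.cell_cycle_scores(norm, s_genes, g2m_genes, seed=0)
        cycling = norm.obs["cycling"].to_numpy()
        called = (out["phase"] != "G1").to_numpy()
        rate_cyc = called[cycling].mean()
        rate_not = called[~cycling].mean()
        assert rate_cyc >= 2.0 * rate_not


class TestEmbeddingRegion:
    def test_full_rectangle_selects_all(self):
        coords = pd.DataFrame({"x": [0, 1, 2], "y": [0, -1, 1]})
        idx = sig.select_embedding_region(coords, (-5, 5, -5, 5))
        assert len(idx) == 3

    def test_membership_matches_enumeration(self):
        rng = np.random.default_rng(0)
        coords = pd.DataFrame(rng.uniform(-2, 2, size=(50, 2)),
                              columns=["x", "y"])
        rect = (-1.0, 0.5, -0.5, 1.5)
        idx = sig.select_embedding_region(coords, rect)
        expected = [i for i in coords.index
                    if rect[0] <= coords.loc[i, "x"] <= rect[1]
                    and rect[2] <= coords.loc[i, "y"] <= rect[3]]
        assert list(idx) == expected

    def test_empty_selection_errors(self):
        coords = pd.DataFrame({"x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError, match="empty"):
            sig.select_embedding_region(coords, (5.0, 5.0, 5.0, 5.0))

    def test_infinite_rectangle_rejected(self):
        coords = pd.DataFrame({"x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError, match="finite"):
            sig.select_embedding_region(coords, (-np.inf, 1, 0, 1))
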