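"""Marker discovery, module scores, adjusted proportion scores, cell cycle.

The adjusted proportion score is the package's bespoke hybrid-state
statistic: for a 50-gene signature, count in each cell the markers expressed
strictly above their per-gene median, divide by the signature size, then
residualize this raw proportion against per-cell transcriptome complexity
(number of detected genes) with a Huber robust linear fit, re-centering the
residuals at the grand mean so the adjusted score stays on the raw [0, 1]
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MarkerTable",
    "RobustFit",
    "find_markers",
    "module_score",
    "combined_luminal_score",
    "robust_linear_fit",
    "adjusted_proportion_score",
    "cell_cycle_scores",
    "select_embedding_region",
]

MarkerTable = pd.DataFrame  # columns: gene, cluster, auc, log2_fc, pct_in, pct_out


def _X(norm) -> np.ndarray:
    return np.asarray(norm.X, dtype=float)


def _auc_one_vs_rest(X: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Per-gene single-gene-classifier AUC from the rank-sum statistic:
    AUC = U / (n_in * n_out), midranks for ties."""
    n_in = int(in_mask.sum())
    n_out = int((~in_mask).sum())
    aucs = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j])
        U = ranks[in_mask].sum() - n_in * (n_in + 1) / 2.0
        aucs[j] = U / (n_in * n_out)
    return aucs


def find_markers(norm, labels, target=None, min_pct: float = 0.40,
                 only_pos: bool = True) -> MarkerTable:
    """Classifier-AUC marker test (one cluster vs the rest).

    For each gene, AUC of the single-gene classifier separating the target
    cluster from all other cells; genes must be expressed (count > 0) in at
    least ``min_pct`` of target cells, and with positive log2 fold change
    when ``only_pos``.  Rows are ordered by decreasing log2 fold change
    within each cluster.  ``target=None`` tests every cluster.
    """
    labels = pd.Series(labels, dtype=object)
    X = _X(norm)
    targets = sorted(labels.unique()) if target is None else [target]
    frames = []
    for t in targets:
        in_mask = (labels == t).to_numpy()
        if in_mask.sum() < 2 or (~in_mask).sum() < 2:
            raise ValueError(f"cluster {t!r} needs >= 2 cells in and out")
        pct_in = (X[in_mask] > 0).mean(axis=0)
        pct_out = (X[~in_mask] > 0).mean(axis=0)
        # Seurat-convention fold change of de-logged means with pseudocount
        mean_in = np.expm1(X[in_mask]).mean(axis=0)
        mean_out = np.expm1(X[~in_mask]).mean(axis=0)
        log2_fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        keep = pct_in > min_pct
        if only_pos:
            keep &= log2_fc > 0
        cols = np.flatnonzero(keep)
        aucs = np.full(X.shape[1], np.nan)
        aucs[cols] = _auc_one_vs_rest(X[:, cols], in_mask)
        df = pd.DataFrame({
            "gene": norm.var_names[cols],
            "cluster": t,
            "auc": aucs[cols],
            "log2_fc": log2_fc[cols],
            "pct_in": pct_in[cols],
            "pct_out": pct_out[cols],
        }).sort_values("log2_fc", ascending=False, kind="stable")
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def top_markers_by_auc(markers: MarkerTable, cluster: str, n: int = 50) -> list:
    """Top-``n`` marker genes of one cluster ranked by AUC."""
    sub = markers[markers["cluster"] == cluster]
    return list(sub.sort_values("auc", ascending=False, kind="stable")
                   .head(n)["gene"])


def module_score(norm, gene_set, n_bins: int = 24, n_ctrl: int = 100,
                 seed: int = 0) -> pd.Series:
    """Expression-bin-matched gene-set score (AddModuleScore convention).

    score = mean expression of the set − mean expression of control genes,
    where controls are drawn per set-gene (``n_ctrl`` each, without
    replacement, fixed seed) from the same average-expression bin; bins are
    ``n_bins`` equal-frequency bins over all genes.
    """
    genes = [g for g in gene_set if g in norm.var_names]
    missing = set(gene_set) - set(genes)
    if missing:
        warnings.warn(f"{len(missing)} gene(s) of the set absent; dropped")
    if not genes:
        raise ValueError("no genes of the set are present in the matrix")
    X = _X(norm)
    avg = X.mean(axis=0)
    n_genes = X.shape[1]
    if n_genes < n_bins:
        warnings.warn(f"only {n_genes} genes for {n_bins} bins; reducing")
        n_bins = max(1, n_genes)
    # equal-frequency (ntile) binning of genes by average expression,
    # stable tie-break by gene order
    order = np.lexsort((np.arange(n_genes), avg))
    bins = np.empty(n_genes, dtype=int)
    bins[order] = (np.arange(n_genes) * n_bins) // n_genes
    rng = np.random.default_rng(seed)
    gene_idx = {g: i for i, g in enumerate(norm.var_names)}
    ctrl: set[int] = set()
    for g in genes:
        b = bins[gene_idx[g]]
        pool = np.flatnonzero(bins == b)
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.array(sorted(ctrl))
    set_idx = np.array([gene_idx[g] for g in genes])
    score = X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=norm.obs_names)


def combined_luminal_score(norm, lum_er_pos_set, lum_er_neg_set,
                           **kwargs) -> pd.Series:
    """Single luminal score from the union of the ER-positive and
    ER-negative luminal signatures."""
    a = [g for g in lum_er_pos_set if g in norm.var_names]
    b = [g for g in lum_er_neg_set if g in norm.var_names]
    if not a and not b:
        raise ValueError("both luminal signatures are empty after filtering")
    if not a or not b:
        warnings.warn("one luminal signature empty after filtering; "
                      "score reduces to the other signature")
    union = sorted(set(a) | set(b))
    return module_score(norm, union, **kwargs)


@dataclass
class RobustFit:
    slope: float
    intercept: float
    residuals: np.ndarray
    weights: np.ndarray
    n_iterations: int
    converged: bool


def robust_linear_fit(x, y, tuning: float = 1.345, tol: float = 1e-8,
                      max_iter: int = 50) -> RobustFit:
    """Huber M-estimator of a straight line via IRLS.

    Weights w = min(1, c·s/|r|) with c = ``tuning`` and s the MAD-based
    robust scale (median |r| / 0.6745), re-estimated each iteration;
    convergence when the maximum coefficient change is below ``tol``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("covariate x is constant; robust fit undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    w = np.ones_like(y)
    converged = False
    it = 0
    y_scale = max(np.median(np.abs(y - np.median(y))), 1e-12)
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        s = np.median(np.abs(r)) / 0.6745
        if s <= 1e-12 * y_scale:      # (near-)exact fit: nothing to reweight
            w = np.ones_like(y)
            converged = True
            break
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, tuning * s / np.abs(r))
        w[np.abs(r) == 0] = 1.0
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ y)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"robust fit did not converge in {max_iter} iterations")
    r = y - X @ beta
    return RobustFit(slope=float(beta[1]), intercept=float(beta[0]),
                     residuals=r, weights=w, n_iterations=it,
                     converged=converged)


def adjusted_proportion_score(norm, marker_set, complexity=None,
                              pooled_median: bool = False):
    """Raw and complexity-adjusted proportion of signature markers expressed.

    Per marker gene g the threshold is the median of g's normalized
    expression over all cells (or a single pooled median over all marker
    values when ``pooled_median``); raw_i = |{g : x_ig > θ_g}| / |markers|
    (strict inequality — ties at the median count as not expressed).
    adjusted_i = Huber-fit residual of raw on complexity, plus mean(raw).
    """
    markers = [g for g in marker_set if g in norm.var_names]
    dropped = set(marker_set) - set(markers)
    if dropped:
        warnings.warn(f"{len(dropped)} marker(s) absent; denominator is "
                      f"{len(markers)}")
    if not markers:
        raise ValueError("no signature markers present in the matrix")
    sub = np.asarray(norm[:, markers].X, dtype=float)
    if pooled_median:
        theta = np.full(len(markers), np.median(sub))
    else:
        theta = np.median(sub, axis=0)
    raw = (sub > theta).sum(axis=1) / len(markers)
    if complexity is None:
        counts = norm.layers["counts"] if "counts" in norm.layers else norm.X
        complexity = (np.asarray(counts) > 0).sum(axis=1)
    complexity = np.asarray(complexity, dtype=float)
    fit = robust_linear_fit(complexity, raw)
    adjusted = fit.residuals + raw.mean()
    idx = norm.obs_names
    return pd.Series(raw, index=idx), pd.Series(adjusted, index=idx), fit


def cell_cycle_scores(norm, s_genes, g2m_genes, seed: int = 0,
                      **kwargs) -> pd.DataFrame:
    """S and G2M module scores and the derived phase call: G1 when both
    scores are negative, otherwise the argmax of (S, G2M)."""
    s = module_score(norm, s_genes, seed=seed, **kwargs)
    g2m = module_score(norm, g2m_genes, seed=seed, **kwargs)
    phase = np.where((s < 0) & (g2m < 0), "G1",
                     np.where(s >= g2m, "S", "G2M"))
    return pd.DataFrame({"S_score": s, "G2M_score": g2m, "phase": phase},
                        index=norm.obs_names)


def select_embedding_region(coords, rectangle) -> pd.Index:
    """Cells inside the closed rectangle (xmin, xmax, ymin, ymax) of a 2-D
    embedding — the programmatic stand-in for interactive region selection."""
    xmin, xmax, ymin, ymax = rectangle
    if not all(np.isfinite([xmin, xmax, ymin, ymax])):
        raise ValueError("rectangle must be finite")
    coords = pd.DataFrame(coords)
    x, y = coords.iloc[:, 0], coords.iloc[:, 1]
    inside = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
    if not inside.any():
        raise ValueError("empty selection: no cells inside the rectangle")
    return coords.index[inside]
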