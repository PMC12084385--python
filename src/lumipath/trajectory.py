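"""Lineage inference, pseudotime, association testing, pattern groups.

Lineages are root-to-leaf paths of the minimum spanning tree over cluster
centroids in PCA space, rooted at the designated origin cluster (BAS).
Pseudotime is arc length along the (optionally refined) piecewise-linear
principal path.  Per-gene association with pseudotime is a cubic B-spline
regression with knots at pseudotime quantiles and a Wald test that all
consecutive differences of knot-anchored fitted values are zero; p-values
use the F(q, n−p) reference and Benjamini–Hochberg adjustment.  Temporal
patterns are classified by average-linkage hierarchical clustering of
rolling-window-smoothed, z-scored profiles, cut into 3 or 6 groups named
after the six conversion patterns (bas/int/lum × early/late).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.interpolate import BSpline
from scipy.optimize import linear_sum_assignment

__all__ = [
    "TrajectoryResult",
    "AssociationResult",
    "PatternGroups",
    "infer_lineages",
    "compute_pseudotime",
    "fit_trajectory",
    "association_test",
    "filter_trajectory_genes",
    "smooth_and_annotate",
    "pattern_groups",
]

PATTERN_NAMES_6 = ("bas_early", "bas_late", "int_early", "int_late",
                   "lum_early", "lum_late")
PATTERN_NAMES_3 = ("bas", "int", "lum")


@dataclass
class TrajectoryResult:
    lineages: list                      # ordered cluster paths from the origin
    centroids: pd.DataFrame             # clusters × PCs
    mst_edges: list
    pseudotime: pd.DataFrame = None     # cells × lineages (NaN off-lineage)
    weights: pd.DataFrame = None        # cells × lineages in {0, 1}
    curves: dict = field(default_factory=dict)  # lineage index → path points


def infer_lineages(embedding, labels, origin: str) -> TrajectoryResult:
    """Root-to-leaf paths of the centroid MST, starting at ``origin``.

    Centroids are cluster means in PCA space; the MST uses Euclidean edge
    weights; lineages are reported in stable (leaf-label-sorted) order.
    """
    labels = pd.Series(labels, dtype=object)
    clusters = sorted(labels.unique())
    if origin not in clusters:
        raise ValueError(f"origin cluster {origin!r} not present")
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for a lineage")
    X = np.asarray(embedding, dtype=float)
    centroids = pd.DataFrame(
        [X[(labels == c).to_numpy()].mean(axis=0) for c in clusters],
        index=clusters)
    G = nx.Graph()
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            G.add_edge(a, b, weight=float(np.linalg.norm(
                centroids.loc[a] - centroids.loc[b])))
    mst = nx.minimum_spanning_tree(G, weight="weight")
    leaves = sorted(c for c in clusters
                    if c != origin and mst.degree(c) == 1)
    lineages = [nx.shortest_path(mst, origin, leaf) for leaf in leaves]
    return TrajectoryResult(lineages=lineages, centroids=centroids,
                            mst_edges=sorted(map(tuple, mst.edges())))


def _project_onto_path(X: np.ndarray, path: np.ndarray):
    """Orthogonal projection of each row of X onto the piecewise-linear
    path; returns (arc-length pseudotime, projected points)."""
    seg_vec = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_d = np.full(X.shape[0], np.inf)
    pt = np.zeros(X.shape[0])
    proj = np.zeros_like(X)
    for s in range(len(seg_vec)):
        v = seg_vec[s]
        L2 = seg_len[s] ** 2
        if L2 == 0:
            frac = np.zeros(X.shape[0])
        else:
            frac = np.clip((X - path[s]) @ v / L2, 0.0, 1.0)
        p = path[s] + frac[:, None] * v
        d = np.linalg.norm(X - p, axis=1)
        better = d < best_d
        best_d[better] = d[better]
        pt[better] = cum[s] + frac[better] * seg_len[s]
        proj[better] = p[better]
    return pt, proj


def compute_pseudotime(embedding, labels, lineage, centroids=None,
                       refine_iterations: int = 10,
                       curve_points: int = 50) -> tuple:
    """Arc-length pseudotime along one lineage's principal path.

    The initial path joins the lineage's cluster centroids; optional
    refinement replaces it with local averages of the on-lineage cells
    ordered by current pseudotime (a discrete principal curve), re-projects,
    and stops after ``refine_iterations`` or when the mean pseudotime shift
    drops below 1e-4 of the path length.  Cells of clusters off the lineage
    get weight 0 and pseudotime NaN.
    """
    labels = pd.Series(labels, dtype=object)
    X = np.asarray(embedding, dtype=float)
    if centroids is None:
        centroids = pd.DataFrame(
            [X[(labels == c).to_numpy()].mean(axis=0) for c in lineage],
            index=lineage)
    path = centroids.loc[list(lineage)].to_numpy(dtype=float)
    on = labels.isin(lineage).to_numpy()
    pt = np.full(X.shape[0], np.nan)
    pt_on, _ = _project_onto_path(X[on], path)
    for _ in range(max(0, refine_iterations)):
        order = np.argsort(pt_on, kind="stable")
        Xo = X[on][order]
        n = Xo.shape[0]
        k = max(2, min(curve_points, n // 3))
        # local-average smoothing: mean coordinates within pseudotime windows
        edges = np.linspace(0, n, k + 1).astype(int)
        new_path = np.array([Xo[a:b].mean(axis=0)
                             for a, b in zip(edges[:-1], edges[1:]) if b > a])
        # anchor the curve at the origin centroid so pseudotime stays rooted
        new_path = np.vstack([path[0], new_path])
        new_pt, _ = _project_onto_path(X[on], new_path)
        total = np.linalg.norm(np.diff(new_path, axis=0), axis=1).sum()
        shift = np.mean(np.abs(new_pt - pt_on))
        pt_on, path = new_pt, new_path
        if shift < 1e-4 * max(total, 1e-12):
            break
    pt[on] = pt_on
    weights = on.astype(float)
    idx = getattr(embedding, "index", pd.RangeIndex(X.shape[0]))
    return (pd.Series(pt, index=idx), pd.Series(weights, index=idx), path)


def fit_trajectory(embedding, labels, origin: str,
                   refine_iterations: int = 10) -> TrajectoryResult:
    """Infer lineages and compute per-lineage pseudotime in one call."""
    res = infer_lineages(embedding, labels, origin)
    pts, ws = {}, {}
    for li, lineage in enumerate(res.lineages, start=1):
        pt, w, path = compute_pseudotime(
            embedding, labels, lineage, centroids=res.centroids,
            refine_iterations=refine_iterations)
        pts[f"lineage{li}"] = pt
        ws[f"lineage{li}"] = w
        res.curves[f"lineage{li}"] = path
    res.pseudotime = pd.DataFrame(pts)
    res.weights = pd.DataFrame(ws)
    return res


def _spline_design(pseudotime: np.ndarray, n_knots: int):
    """Cubic B-spline design with knots at pseudotime quantiles; returns
    (design matrix, knot locations, full knot vector)."""
    qs = np.linspace(0.0, 1.0, n_knots)
    knots = np.quantile(pseudotime, qs)
    knots = np.unique(knots)
    if len(knots) < 2:
        raise ValueError("degenerate pseudotime: all values identical")
    t = np.concatenate([[knots[0]] * 3, knots, [knots[-1]] * 3])
    x = np.clip(pseudotime, knots[0], knots[-1])
    D = BSpline.design_matrix(x, t, k=3).toarray()
    return D, knots, t


@dataclass
class AssociationResult:
    table: pd.DataFrame                 # gene, wald_stat, p_value, adj_p
    knots: np.ndarray
    coefficients: pd.DataFrame          # genes × spline coefficients
    fitted_at_knots: pd.DataFrame


def association_test(norm_expr: pd.DataFrame, pseudotime,
                     n_knots: int = 8) -> AssociationResult:
    """Spline-regression Wald test of expression change along pseudotime.

    Per gene: fit expression ~ cubic B-spline(pseudotime, knots at
    quantiles); the statistic tests that all consecutive differences of the
    fitted values at the knots are zero (consecutive-contrast form); BH
    adjustment across genes.  The reported ``amplitude`` (range of the
    fitted values at the knots, log-expression units) supports an optional
    effect-size floor on top of significance.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    ok = np.isfinite(pseudotime)
    if ok.sum() < 30:
        raise ValueError("pseudotime defined for fewer than 30 cells")
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    Y = np.asarray(norm_expr, dtype=float)[ok]
    x = pseudotime[ok]
    D, knots, t = _spline_design(x, n_knots)
    n, p = D.shape
    DtD = D.T @ D
    if np.linalg.matrix_rank(DtD) < p:
        raise np.linalg.LinAlgError("singular spline design (degenerate "
                                    "pseudotime distribution)")
    DtD_inv = np.linalg.inv(DtD)
    B = DtD_inv @ D.T @ Y                       # p × genes
    resid = Y - D @ B
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    Dk = BSpline.design_matrix(knots, t, k=3).toarray()   # knots × p
    C = np.diff(Dk, axis=0)                     # consecutive contrasts, q × p
    q = np.linalg.matrix_rank(C)
    M = C @ DtD_inv @ C.T
    M_inv = np.linalg.pinv(M)
    CB = C @ B                                  # q × genes
    wald = np.einsum("qg,qr,rg->g", CB, M_inv, CB) / np.maximum(sigma2, 1e-300)
    # a numerically constant gene has nothing to test: statistic 0, p = 1
    null_scale = np.maximum((Y ** 2).mean(axis=0), 1e-12)
    is_const = sigma2 <= 1e-14 * null_scale
    wald[is_const] = 0.0
    fstat = wald / q
    pvals = stats.f.sf(fstat, q, dof)
    pvals[is_const] = 1.0
    from statsmodels.stats.multitest import multipletests
    adj = multipletests(pvals, method="fdr_bh")[1]
    genes = list(getattr(norm_expr, "columns", range(Y.shape[1])))
    fitted_knots = Dk @ B                       # knots × genes
    amplitude = fitted_knots.max(axis=0) - fitted_knots.min(axis=0)
    table = pd.DataFrame({"gene": genes, "wald_stat": wald,
                          "p_value": pvals, "adj_p": adj,
                          "amplitude": amplitude}) \
        .sort_values("wald_stat", ascending=False, kind="stable") \
        .reset_index(drop=True)
    return AssociationResult(
        table=table, knots=knots,
        coefficients=pd.DataFrame(B.T, index=genes),
        fitted_at_knots=pd.DataFrame(fitted_knots.T, index=genes,
                                     columns=[f"knot{i}" for i in
                                              range(len(knots))]))


def filter_trajectory_genes(counts, min_count: int = 1,
                            min_cells: int = 20) -> list:
    """Genes with a count of at least ``min_count`` in at least
    ``min_cells`` cells (inclusive bounds)."""
    X = np.asarray(counts, dtype=float)
    keep = (X >= min_count).sum(axis=0) >= min_cells
    genes = getattr(counts, "columns", pd.RangeIndex(X.shape[1]))
    return list(pd.Index(genes)[keep])


def smooth_and_annotate(expr: pd.DataFrame, pseudotime, labels,
                        window: int | None = None, step: int = 1):
    """Rolling-window smoothing along pseudotime with per-bin modal labels.

    Cells are ordered by (pseudotime, cell id); per gene a rolling mean over
    ``window`` consecutive cells advances by ``step``; each bin is annotated
    with its most common cluster label (ties go to the label of the earliest
    cell in the bin).  Returns (genes × bins smoothed matrix, bin labels).
    """
    labels = pd.Series(labels, dtype=object)
    pt = pd.Series(np.asarray(pseudotime, dtype=float), index=expr.index)
    n = len(expr)
    if window is None:
        window = int(np.ceil(n / 20))
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > n:
        raise ValueError(f"window {window} exceeds {n} cells")
    order = pt.reset_index(drop=True).sort_values(kind="stable").index
    E = expr.to_numpy(dtype=float)[order]
    lab = labels.to_numpy()[order]
    starts = np.arange(0, n - window + 1, step)
    from numpy.lib.stride_tricks import sliding_window_view
    windows = sliding_window_view(E, window, axis=0)[starts]   # bins × genes × window
    smoothed = windows.mean(axis=2).T                          # genes × bins
    bin_labels = []
    for s in starts:
        chunk = lab[s: s + window]
        counts = pd.Series(chunk).value_counts()
        top = counts.max()
        tied = set(counts.index[counts == top])
        for lbl in chunk:                     # earliest cell among the tied
            if lbl in tied:
                bin_labels.append(lbl)
                break
    smoothed = pd.DataFrame(smoothed, index=expr.columns,
                            columns=[f"bin{1 + i}" for i in range(len(starts))])
    return smoothed, bin_labels


@dataclass
class PatternGroups:
    groups: pd.Series                   # gene → pattern name
    linkage: np.ndarray
    smoothed: pd.DataFrame
    group_profiles: pd.DataFrame        # pattern name → mean z-profile


def _prototypes(n_bins: int, k: int) -> pd.DataFrame:
    """Analytic z-scored prototype profiles on the bin grid used to name
    pattern groups deterministically."""
    u = np.linspace(0.0, 1.0, n_bins)

    def sig(c, sign):
        return sign / (1.0 + np.exp(12.0 * (u - c)))

    def bump(c):
        return np.exp(-((u - c) / 0.15) ** 2)

    if k == 6:
        raw = {"bas_early": sig(0.25, 1), "bas_late": sig(0.70, 1),
               "int_early": bump(0.35), "int_late": bump(0.65),
               "lum_early": -sig(0.30, 1), "lum_late": -sig(0.75, 1)}
    elif k == 3:
        raw = {"bas": sig(0.5, 1), "int": bump(0.5), "lum": -sig(0.5, 1)}
    else:
        raise ValueError("prototype naming defined for k in {3, 6}")
    Z = pd.DataFrame(raw).T
    return Z.sub(Z.mean(axis=1), axis=0).div(Z.std(axis=1), axis=0)


def pattern_groups(smoothed: pd.DataFrame, k: int = 6) -> PatternGroups:
    """Average-linkage hierarchical clustering of z-scored smoothed profiles
    cut into ``k`` groups, named by matching group mean profiles to
    prototype conversion patterns (Hungarian assignment on correlation)."""
    if k > len(smoothed):
        raise ValueError(f"k={k} exceeds {len(smoothed)} genes")
    Z = smoothed.to_numpy(dtype=float)
    mu = Z.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Zs = (Z - mu) / sd
    link = linkage(Zs, method="average", metric="euclidean")
    raw_groups = fcluster(link, t=k, criterion="maxclust")
    group_ids = np.unique(raw_groups)
    profiles = np.array([Zs[raw_groups == g].mean(axis=0) for g in group_ids])
    if len(group_ids) == k and k in (3, 6):
        prot = _prototypes(Z.shape[1], k)
        corr = np.zeros((len(group_ids), k))
        for i, prof in enumerate(profiles):
            for j, name in enumerate(prot.index):
                pv = prot.loc[name].to_numpy()
                c = np.corrcoef(prof, pv)[0, 1]
                corr[i, j] = 0.0 if np.isnan(c) else c
        rows, cols = linear_sum_assignment(-corr)
        name_of = {group_ids[r]: prot.index[c] for r, c in zip(rows, cols)}
    else:
        warnings.warn("tree cut yielded a group count without a fixed "
                      "vocabulary; using positional names")
        peaks = profiles.argmax(axis=1)
        order = np.argsort(peaks, kind="stable")
        name_of = {group_ids[g]: f"group{i + 1}"
                   for i, g in enumerate(order)}
    names = pd.Series([name_of[g] for g in raw_groups], index=smoothed.index)
    prof_df = pd.DataFrame(profiles, index=[name_of[g] for g in group_ids],
                           columns=smoothed.columns)
    return PatternGroups(groups=names, linkage=link, smoothed=smoothed,
                         group_profiles=prof_df)
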