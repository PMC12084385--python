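"""Per-cell regulon activity (ranking AUC) and regulon specificity scores.

Regulons (a transcription factor plus its target genes, TF included by
convention) are taken as input — from file or from simulator ground truth.
Activity per cell is the area under the gene-recovery curve over the top
5% of the cell's expression ranking (the AUCell statistic); cluster
specificity is RSS = 1 − sqrt(JSD) between a regulon's normalized activity
distribution over cells and a cluster's indicator distribution, with the
Jensen–Shannon divergence in base-2 logs so RSS ∈ [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

__all__ = [
    "Regulon",
    "read_regulons",
    "aucell_score",
    "aucell_matrix",
    "regulon_specificity_score",
    "top_regulons_per_cluster",
]


@dataclass(frozen=True)
class Regulon:
    tf: str
    targets: frozenset

    def __post_init__(self):
        if not self.targets:
            raise ValueError(f"regulon {self.tf!r} has an empty target set")


def read_regulons(path) -> list[Regulon]:
    """Read regulons from TSV (columns tf, target; one pair per line) or
    JSON ({tf: [targets...]})."""
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            data = json.load(fh)
        return [Regulon(tf, frozenset(tgts)) for tf, tgts in data.items()]
    df = pd.read_csv(path, sep="\t", header=None, names=["tf", "target"],
                     comment="#")
    return [Regulon(tf, frozenset(grp["target"]))
            for tf, grp in df.groupby("tf", sort=True)]


def _rank_matrix(norm) -> np.ndarray:
    """Per-cell ranking of genes by decreasing expression; ties broken by
    lexicographic gene id for determinism.  Entry [i, j] = rank (0-based)
    of gene j in cell i."""
    X = np.asarray(norm.X, dtype=float)
    name_rank = np.argsort(np.argsort(norm.var_names.to_numpy()))
    order = np.lexsort((np.broadcast_to(name_rank, X.shape), -X), axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(X.shape[0])[:, None]
    ranks[rows, order] = np.arange(X.shape[1])[None, :]
    return ranks


def _aucell_from_ranks(ranks: np.ndarray, hit_cols: np.ndarray,
                       window: int) -> np.ndarray:
    """AUC of the step recovery curve: sum over the top ``window`` ranks of
    the cumulative hit count, normalized by its maximum attainable value."""
    m = len(hit_cols)
    if m == 0:
        return np.zeros(ranks.shape[0])
    hit_ranks = ranks[:, hit_cols]                      # cells × hits
    inside = hit_ranks < window
    # each hit at rank r contributes (window - r) to the step-sum
    raw = np.where(inside, window - hit_ranks, 0).sum(axis=1)
    m_eff = min(m, window)
    i = np.arange(1, window + 1)
    max_raw = np.minimum(i, m_eff).sum()
    return raw / max_raw


def aucell_score(norm, regulon, top_fraction: float = 0.05) -> pd.Series:
    """Per-cell AUCell activity of one regulon."""
    if isinstance(regulon, Regulon):
        targets = regulon.targets
    else:
        targets = frozenset(regulon)
    hit_cols = np.flatnonzero(norm.var_names.isin(targets))
    if len(hit_cols) == 0:
        warnings.warn("regulon has no genes in the matrix; activity is zero")
        return pd.Series(0.0, index=norm.obs_names)
    window = int(np.ceil(top_fraction * norm.n_vars))
    ranks = _rank_matrix(norm)
    return pd.Series(_aucell_from_ranks(ranks, hit_cols, window),
                     index=norm.obs_names)


def aucell_matrix(norm, regulons, top_fraction: float = 0.05) -> pd.DataFrame:
    """Cells × regulons AUCell activity matrix (ranking computed once)."""
    ranks = _rank_matrix(norm)
    window = int(np.ceil(top_fraction * norm.n_vars))
    out = {}
    for reg in regulons:
        tf, targets = (reg.tf, reg.targets) if isinstance(reg, Regulon) \
            else (reg, regulons[reg])
        hit_cols = np.flatnonzero(norm.var_names.isin(frozenset(targets)))
        if len(hit_cols) == 0:
            warnings.warn(f"regulon {tf!r} has no genes in the matrix")
        out[tf] = _aucell_from_ranks(ranks, hit_cols, window)
    return pd.DataFrame(out, index=norm.obs_names)


def regulon_specificity_score(activity: pd.DataFrame, labels) -> pd.DataFrame:
    """RSS(r, c) = 1 − sqrt(JSD(p_r, q_c)), base-2 logs.

    p_r is regulon r's activity column normalized to sum 1 over cells and
    q_c the indicator of cluster c normalized likewise.  All-zero activity
    columns yield NaN with a warning.
    """
    labels = pd.Series(labels, dtype=object)
    if len(labels) != len(activity):
        raise ValueError("labels and activity are misaligned")
    clusters = sorted(labels.unique())
    rss = pd.DataFrame(index=activity.columns, columns=clusters, dtype=float)
    A = activity.to_numpy(dtype=float)
    for ci, c in enumerate(clusters):
        q = (labels == c).to_numpy(dtype=float)
        q /= q.sum()
        for ri, r in enumerate(activity.columns):
            p = A[:, ri]
            tot = p.sum()
            if tot <= 0:
                if ci == 0:
                    warnings.warn(f"regulon {r!r} has all-zero activity; "
                                  "RSS undefined")
                rss.loc[r, c] = np.nan
                continue
            rss.loc[r, c] = 1.0 - jensenshannon(p / tot, q, base=2)
    return rss


def top_regulons_per_cluster(rss: pd.DataFrame, n: int = 50) -> dict:
    """Per-cluster top-``n`` regulons by RSS, pairwise/multiway overlap
    counts for Venn-style reporting, and cluster-exclusive regulons."""
    if rss.shape[0] < n:
        warnings.warn(f"only {rss.shape[0]} regulons scored; returning all")
        n = rss.shape[0]
    tops = {}
    for c in rss.columns:
        col = rss[c].dropna()
        order = col.sort_values(ascending=False, kind="stable")
        tops[c] = list(order.index[:n])
    clusters = list(rss.columns)
    overlaps = {}
    for k in range(2, len(clusters) + 1):
        for combo in combinations(clusters, k):
            shared = set(tops[combo[0]])
            for c in combo[1:]:
                shared &= set(tops[c])
            overlaps[" & ".join(map(str, combo))] = len(shared)
    exclusive = {}
    for c in clusters:
        others = set().union(*(tops[o] for o in clusters if o != c)) \
            if len(clusters) > 1 else set()
        exclusive[c] = sorted(set(tops[c]) - others)
    return {"top": tops, "overlap": overlaps, "exclusive": exclusive}
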