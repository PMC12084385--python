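"""Cell/gene filtering, normalization, HVG selection and scaling.

All threshold comparisons are strict: a gene detected in exactly
``min_cells_per_gene`` cells is removed, a cell with exactly the minimum
feature count or total is removed, a mitochondrial fraction exactly at the
ceiling is removed.  Filters operate on raw counts and are idempotent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "EmptyResultError",
    "basic_gene_cell_filter",
    "qc_cell_filter",
    "contaminant_filter",
    "log_normalize",
    "select_hvg",
    "scale_features",
]


class EmptyResultError(RuntimeError):
    """A filter removed every cell or every gene."""


@dataclass
class QCThresholds:
    """Quality-control thresholds (all comparisons strict).

    Defaults: genes kept when detected in >2 cells; cells kept with >200
    detected features at the basic stage, then <10% mitochondrial reads,
    >1400 features and >100,000 total counts; stromal cells (Epcam < 2) and
    salivary cells (Dcpp1 > 1) flagged for removal.
    """

    min_cells_per_gene: int = 2
    min_features_basic: int = 200
    max_mito_fraction: float = 0.10
    min_features: int = 1400
    min_total_counts: int = 100_000
    contaminant_rules: list = field(default_factory=lambda: [
        ("Epcam", "<", 2), ("Dcpp1", ">", 1)])

    def __post_init__(self):
        for name in ("min_cells_per_gene", "min_features_basic",
                     "min_features", "min_total_counts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be a proportion")
        for gene, cmp_, thr in self.contaminant_rules:
            if cmp_ not in ("<", ">"):
                raise ValueError(f"comparator for {gene} must be '<' or '>'")


def _counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    return np.asarray(X)


def basic_gene_cell_filter(raw: ad.AnnData,
                           thresholds: QCThresholds | None = None) -> ad.AnnData:
    """Keep genes detected in > ``min_cells_per_gene`` cells and cells with
    > ``min_features_basic`` detected genes (strict inequalities)."""
    thr = thresholds or QCThresholds()
    X = _counts(raw)
    gene_keep = (X > 0).sum(axis=0) > thr.min_cells_per_gene
    X = X[:, gene_keep]
    cell_keep = (X > 0).sum(axis=1) > thr.min_features_basic
    logger.info("basic filter: %d/%d genes, %d/%d cells retained",
                gene_keep.sum(), raw.n_vars, cell_keep.sum(), raw.n_obs)
    if not gene_keep.any() or not cell_keep.any():
        raise EmptyResultError(
            f"basic filter removed everything "
            f"({gene_keep.sum()} genes, {cell_keep.sum()} cells left)")
    return raw[cell_keep, gene_keep].copy()


def qc_cell_filter(adata: ad.AnnData,
                   thresholds: QCThresholds | None = None,
                   mito_genes=None) -> ad.AnnData:
    """Remove cells failing the mito-fraction / feature-count / total-count
    criteria; the full per-cell QC report lands in ``.uns["qc_report"]``.

    Mitochondrial genes default to the case-insensitive ``mt-`` name prefix.
    """
    thr = thresholds or QCThresholds()
    X = _counts(adata)
    if mito_genes is None:
        mito_mask = adata.var_names.str.lower().str.startswith("mt-")
    else:
        mito_mask = adata.var_names.isin(list(mito_genes))
    totals = X.sum(axis=1)
    n_features = (X > 0).sum(axis=1)
    if mito_mask.sum() == 0:
        warnings.warn("no mitochondrial genes found; mito criterion skipped")
        mito_frac = np.zeros(adata.n_obs)
        pass_mito = np.ones(adata.n_obs, dtype=bool)
    else:
        mito_frac = X[:, np.asarray(mito_mask)].sum(axis=1) / np.maximum(totals, 1)
        pass_mito = mito_frac < thr.max_mito_fraction
    pass_feat = n_features > thr.min_features
    pass_total = totals > thr.min_total_counts
    report = pd.DataFrame({
        "mito_fraction": mito_frac,
        "n_features": n_features,
        "total_counts": totals,
        "pass_mito": pass_mito,
        "pass_features": pass_feat,
        "pass_total": pass_total,
    }, index=adata.obs_names)
    keep = pass_mito & pass_feat & pass_total
    logger.info("QC filter: %d/%d cells retained", keep.sum(), adata.n_obs)
    if not keep.any():
        raise EmptyResultError("QC filter removed every cell")
    out = adata[keep].copy()
    out.uns["qc_report"] = report
    return out


def contaminant_filter(adata: ad.AnnData, rules=None) -> ad.AnnData:
    """Remove cells matching ANY contaminant rule, e.g. stromal cells with
    ``Epcam < 2`` counts or salivary cells with ``Dcpp1 > 1`` counts."""
    rules = rules if rules is not None else QCThresholds().contaminant_rules
    X = _counts(adata)
    flagged = np.zeros(adata.n_obs, dtype=bool)
    for gene, cmp_, threshold in rules:
        if gene not in adata.var_names:
            warnings.warn(f"contaminant rule gene {gene!r} absent; rule skipped")
            continue
        col = X[:, adata.var_names.get_loc(gene)]
        flagged |= (col < threshold) if cmp_ == "<" else (col > threshold)
    logger.info("contaminant filter: %d cells removed", flagged.sum())
    if flagged.all():
        raise EmptyResultError("contaminant filter removed every cell")
    return adata[~flagged].copy()


def log_normalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Library-size normalize to ``scale_factor`` counts per cell and take
    ``ln(1 + x)``; raw counts are preserved in ``.layers["counts"]``."""
    X = _counts(adata).astype(float)
    totals = X.sum(axis=1)
    if np.any(totals <= 0):
        bad = adata.obs_names[totals <= 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts; cannot normalize")
    out = adata.copy()
    out.layers["counts"] = _counts(adata).copy()
    out.X = np.log1p(X / totals[:, None] * scale_factor)
    out.uns["scale_factor"] = scale_factor
    return out


def select_hvg(norm: ad.AnnData, n: int = 2000, lowess_frac: float = 0.3):
    """Top-``n`` highly variable genes by trend-standardized variance ("vst").

    Per-gene raw-count variance is standardized against a mean–variance
    trend fitted on log10 scale (lowess), with standardized values clipped
    at sqrt(n_cells); genes are returned in decreasing rank order and also
    flagged in ``norm.var["highly_variable"]``.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if n > norm.n_vars:
        raise ValueError(f"requested {n} HVGs but only {norm.n_vars} genes present")
    X = _counts(norm).astype(float)
    n_cells = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    not_const = var > 0
    # trend: log10(var) ~ lowess(log10(mean)) over genes with positive variance
    lm = np.log10(mean[not_const])
    lv = np.log10(var[not_const])
    fitted = lowess(lv, lm, frac=lowess_frac, return_sorted=False)
    sd_reg = np.zeros_like(mean)
    sd_reg[not_const] = np.sqrt(10.0 ** fitted)
    std_var = np.zeros_like(mean)
    clip = np.sqrt(n_cells)
    for j in np.flatnonzero(not_const):
        z = (X[:, j] - mean[j]) / sd_reg[j]
        np.clip(z, -clip, clip, out=z)
        std_var[j] = np.sum(z * z) / (n_cells - 1)
    order = np.argsort(-std_var, kind="stable")
    hvg = list(norm.var_names[order[:n]])
    norm.var["variances_norm"] = std_var
    norm.var["highly_variable"] = norm.var_names.isin(hvg)
    return hvg


def scale_features(norm: ad.AnnData, genes=None, clip: float = 10.0) -> pd.DataFrame:
    """Z-score each gene across cells (mean 0, unit variance), clipping
    standardized values at ``+clip``; constant genes scale to all-zeros."""
    genes = list(genes) if genes is not None else list(norm.var_names)
    missing = [g for g in genes if g not in norm.var_names]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    sub = norm[:, genes]
    X = np.asarray(sub.X, dtype=float).copy()
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} zero-variance genes scaled to zeros")
    sd_safe = np.where(const, 1.0, sd)
    Z = (X - mean) / sd_safe
    Z[:, const] = 0.0
    np.minimum(Z, clip, out=Z)
    return pd.DataFrame(Z, index=norm.obs_names, columns=genes)
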