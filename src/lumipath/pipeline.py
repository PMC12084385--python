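"""End-to-end orchestration: simulate → QC → cluster → score → regulons →
trajectory → transfer, with a single config, structured logging and a JSON
run report.

Each stage reads from and writes to an in-memory state (an annotated
AnnData plus side tables); ``run_pipeline`` executes the enabled stages in
dependency order, persists artifacts as CSV/TSV under ``outdir`` and a
machine-readable report as ``report.json``.  Everything is deterministic
given the config seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from . import qc as lqc
from . import signatures as lsig
from . import regulons as lreg
from . import trajectory as ltraj
from . import transfer as ltrans
from .cluster import (cluster_cells, integrate_batches, name_clusters,
                      run_pca, run_umap, subcluster)
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_packaged_signature", "STAGES"]

STAGES = ("simulate", "qc", "cluster", "score", "regulons", "trajectory",
          "transfer")


def load_packaged_signature(name: str) -> list:
    """Load one of the gene lists shipped with the package (data/*.txt)."""
    text = resources.files("lumipath.data").joinpath(name).read_text()
    return [l.strip() for l in text.splitlines()
            if l.strip() and not l.startswith("#")]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study's parameter values
    (resolutions 0.5/0.6, 30 PCs, UMAP spread 0.4, 2000/4000 HVGs,
    min.pct 0.40, 8 knots, top 50 markers, top 40 genes, 3/6 pattern cuts).
    Unknown keys in a config file are rejected."""

    outdir: str = "lumipath_run"
    seed: int = 0
    stages: tuple = STAGES
    input_dir: str | None = None          # load a bundle instead of simulating
    sim: SimConfig = field(default_factory=SimConfig)
    qc: lqc.QCThresholds = field(default_factory=lqc.QCThresholds)
    exclude_plates: tuple = ()            # metadata-level exclusions
    n_hvg: int = 2000
    n_pcs: int = 30
    k_neighbors: int = 20
    resolution: float = 0.5
    subcluster_resolution: float = 0.6
    umap_spread: float = 0.4
    reference_batch: str = "batch1"
    min_pct: float = 0.40
    n_top_markers: int = 50
    regulon_file: str | None = None       # None: use simulator truth regulons
    aucell_top_fraction: float = 0.05
    n_top_regulons: int = 50
    trajectory_origin: str = "BAS"
    n_assoc_hvg: int = 4000
    n_knots: int = 8
    n_top_genes: int = 40
    smoothing_window: int | None = None   # default ceil(n_cells / 20)
    assoc_alpha: float = 0.05
    #: effect-size floor for the pattern heatmap: keep significant genes
    #: whose fitted range along pseudotime is at least a 2-fold change
    assoc_min_amplitude: float = 0.6931471805599453
    transfer_query_dir: str | None = None  # None: simulate a sibling dataset
    transfer_k: int = 30

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d and isinstance(d["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(d["sim"]) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            d["sim"] = SimConfig(**d["sim"])
        if "qc" in d and isinstance(d["qc"], dict):
            qc_known = {f.name for f in dataclasses.fields(lqc.QCThresholds)}
            bad = set(d["qc"]) - qc_known
            if bad:
                raise ValueError(f"unknown qc config keys: {sorted(bad)}")
            d["qc"] = lqc.QCThresholds(**d["qc"])
        if "stages" in d:
            bad = set(d["stages"]) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and return the run
    report (also written to ``outdir/report.json``)."""
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages_run": [], "seed": cfg.seed}
    state: dict = {}
    order = [s for s in STAGES if s in cfg.stages]
    for stage in order:
        logger.info("=== stage %s ===", stage)
        try:
            _STAGE_FUNCS[stage](cfg, state, report, outdir)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        report["stages_run"].append(stage)
    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=_jsonable)
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def _stage_simulate(cfg, state, report, outdir):
    if cfg.input_dir:
        adata = lio.read_bundle(cfg.input_dir)
    else:
        adata = simulate_dataset(cfg.sim)
        lio.write_bundle(adata, outdir / "bundle")
    state["raw"] = adata
    report["simulate"] = {
        "n_cells": int(adata.n_obs), "n_genes": int(adata.n_vars),
        "source": cfg.input_dir or "simulated",
    }


def _stage_qc(cfg, state, report, outdir):
    adata = state["raw"]
    if cfg.exclude_plates and "plate" in adata.obs:
        keep = ~adata.obs["plate"].isin(cfg.exclude_plates)
        adata = adata[keep].copy()
    n0 = adata.n_obs
    step1 = lqc.basic_gene_cell_filter(adata, cfg.qc)
    step2 = lqc.qc_cell_filter(step1, cfg.qc)
    step3 = lqc.contaminant_filter(step2, cfg.qc.contaminant_rules)
    norm = lqc.log_normalize(step3)
    hvg = lqc.select_hvg(norm, n=min(cfg.n_hvg, norm.n_vars))
    state["norm"] = norm
    state["hvg"] = hvg
    state["scaled"] = lqc.scale_features(norm, hvg)
    step2.uns["qc_report"].to_csv(outdir / "qc_report.csv")
    report["qc"] = {
        "n_cells_input": int(n0),
        "n_cells_after_basic": int(step1.n_obs),
        "n_genes_after_basic": int(step1.n_vars),
        "n_cells_after_qc": int(step2.n_obs),
        "n_cells_after_contaminant": int(step3.n_obs),
        "n_hvg": len(hvg),
    }


def _stage_cluster(cfg, state, report, outdir):
    norm, scaled = state["norm"], state["scaled"]
    batches = norm.obs["batch"].astype(str).to_numpy() \
        if "batch" in norm.obs else np.repeat("batch1", norm.n_obs)
    if len(np.unique(batches)) > 1:
        emb = integrate_batches(scaled, batches, cfg.reference_batch,
                                n_pcs=cfg.n_pcs)
    else:
        emb = run_pca(scaled, n_components=cfg.n_pcs).scores
    labels = cluster_cells(emb, resolution=cfg.resolution,
                           k_neighbors=cfg.k_neighbors, seed=cfg.seed)
    # the study splits a mixed basal/intermediate cluster at resolution 0.6
    # when the global resolution yields fewer than five clusters
    if labels.nunique() == 4:
        named0, info0 = name_clusters(norm, labels,
                                      facs=norm.obs.get("facs_gate"))
        target = labels[named0 == "BAS"].iloc[0]
        labels = subcluster(emb, labels, target,
                            resolution=cfg.subcluster_resolution,
                            k_neighbors=min(cfg.k_neighbors,
                                            (labels == target).sum() - 1),
                            seed=cfg.seed)
    named, info = name_clusters(norm, labels, facs=norm.obs.get("facs_gate"))
    umap = run_umap(emb, spread=cfg.umap_spread, seed=cfg.seed)
    norm.obs["cluster_raw"] = labels.to_numpy()
    norm.obs["cluster"] = named.to_numpy()
    state["embedding"] = emb
    state["umap"] = umap
    emb.to_csv(outdir / "pca_embedding.csv")
    umap.to_csv(outdir / "umap.csv")
    pd.DataFrame({"cluster_raw": labels.to_numpy(),
                  "cluster": named.to_numpy()}, index=norm.obs_names) \
        .to_csv(outdir / "clusters.csv")
    report["cluster"] = {
        "n_clusters": int(named.nunique()),
        "cluster_sizes": named.value_counts().to_dict(),
        "naming": info["mapping"],
    }


def _stage_score(cfg, state, report, outdir):
    norm = state["norm"]
    labels = norm.obs["cluster"]
    markers = lsig.find_markers(norm, labels, min_pct=cfg.min_pct)
    markers.to_csv(outdir / "markers.csv", index=False)
    bas_sig = lsig.top_markers_by_auc(markers, "BAS", n=cfg.n_top_markers)
    lum_sig = lsig.top_markers_by_auc(markers, "HRneg", n=cfg.n_top_markers)
    raw_bas, adj_bas, _ = lsig.adjusted_proportion_score(norm, bas_sig)
    raw_lum, adj_lum, _ = lsig.adjusted_proportion_score(norm, lum_sig)
    basal_set = load_packaged_signature("signature_basal_synthetic.txt")
    lum_pos = load_packaged_signature("signature_lum_er_pos_synthetic.txt")
    lum_neg = load_packaged_signature("signature_lum_er_neg_synthetic.txt")
    bas_module = lsig.module_score(norm, [g for g in basal_set
                                          if g in norm.var_names],
                                   seed=cfg.seed)
    lum_module = lsig.combined_luminal_score(norm, lum_pos, lum_neg,
                                             seed=cfg.seed)
    s_genes = [g for g in load_packaged_signature("cc_s_genes.txt")
               if g in norm.var_names]
    g2m_genes = [g for g in load_packaged_signature("cc_g2m_genes.txt")
                 if g in norm.var_names]
    if "cc_class" in norm.var and (len(s_genes) < 5 or len(g2m_genes) < 5):
        s_genes = list(norm.var_names[norm.var["cc_class"] == "S"])
        g2m_genes = list(norm.var_names[norm.var["cc_class"] == "G2M"])
    cc = lsig.cell_cycle_scores(norm, s_genes, g2m_genes, seed=cfg.seed)
    scores = pd.DataFrame({
        "raw_prop_bas": raw_bas, "adj_prop_bas": adj_bas,
        "raw_prop_lum": raw_lum, "adj_prop_lum": adj_lum,
        "basal_module": bas_module, "luminal_module": lum_module,
        "S_score": cc["S_score"], "G2M_score": cc["G2M_score"],
        "phase": cc["phase"],
    })
    scores.to_csv(outdir / "signature_scores.csv")
    for col in scores.columns:
        norm.obs[col] = scores[col].to_numpy()
    state["markers"] = markers
    report["score"] = {
        "n_bas_markers": len(bas_sig),
        "n_lum_markers": len(lum_sig),
        "phase_counts": cc["phase"].value_counts().to_dict(),
        "mean_adj_prop_bas_by_cluster":
            adj_bas.groupby(labels.to_numpy()).mean().round(4).to_dict(),
        "mean_adj_prop_lum_by_cluster":
            adj_lum.groupby(labels.to_numpy()).mean().round(4).to_dict(),
    }


def _stage_regulons(cfg, state, report, outdir):
    norm = state["norm"]
    if cfg.regulon_file:
        regs = lreg.read_regulons(cfg.regulon_file)
    elif "regulons" in norm.uns:
        regs = [lreg.Regulon(tf, frozenset(t))
                for tf, t in norm.uns["regulons"].items()]
    else:
        raise ValueError("no regulon_file given and no truth regulons present")
    activity = lreg.aucell_matrix(norm, regs,
                                  top_fraction=cfg.aucell_top_fraction)
    rss = lreg.regulon_specificity_score(activity, norm.obs["cluster"])
    tops = lreg.top_regulons_per_cluster(
        rss, n=min(cfg.n_top_regulons, rss.shape[0]))
    activity.to_csv(outdir / "regulon_activity.csv")
    rss.to_csv(outdir / "regulon_rss.csv")
    state["activity"], state["rss"] = activity, rss
    report["regulons"] = {
        "n_regulons": int(activity.shape[1]),
        "top_regulons": {c: v[:5] for c, v in tops["top"].items()},
        "exclusive_regulons": tops["exclusive"],
    }


def _stage_trajectory(cfg, state, report, outdir):
    norm, emb = state["norm"], state["embedding"]
    labels = norm.obs["cluster"]
    traj = ltraj.fit_trajectory(emb, labels, cfg.trajectory_origin)
    pt = traj.pseudotime["lineage1"]
    cells = pt.index[pt.notna()]
    counts = pd.DataFrame(np.asarray(norm[cells].layers["counts"]),
                          index=cells, columns=norm.var_names)
    traj_genes = ltraj.filter_trajectory_genes(counts)
    hvg_all = lqc.select_hvg(norm.copy(),
                             n=min(cfg.n_assoc_hvg, norm.n_vars))
    assoc_genes = [g for g in hvg_all if g in set(traj_genes)]
    expr = pd.DataFrame(np.asarray(norm[cells, assoc_genes].X),
                        index=cells, columns=assoc_genes)
    assoc = ltraj.association_test(expr, pt.loc[cells], n_knots=cfg.n_knots)
    sig = assoc.table[(assoc.table["adj_p"] < cfg.assoc_alpha)
                      & (assoc.table["amplitude"] >= cfg.assoc_min_amplitude)]
    sig_genes = list(sig["gene"])
    smoothed, bins = ltraj.smooth_and_annotate(
        expr[sig_genes], pt.loc[cells], labels.loc[cells],
        window=cfg.smoothing_window)
    pats6 = ltraj.pattern_groups(smoothed, k=6)
    top_genes = list(sig["gene"].head(cfg.n_top_genes))
    pats3 = ltraj.pattern_groups(smoothed.loc[top_genes], k=3)
    traj.pseudotime.to_csv(outdir / "pseudotime.csv")
    assoc.table.to_csv(outdir / "association.csv", index=False)
    smoothed.to_csv(outdir / "smoothed_expression.tsv", sep="\t")
    pd.Series(bins, name="bin_cluster").to_csv(outdir / "bin_annotation.tsv",
                                               sep="\t")
    pd.DataFrame({"pattern6": pats6.groups}).to_csv(outdir / "patterns_k6.csv")
    pd.DataFrame({"pattern3": pats3.groups}).to_csv(outdir / "patterns_k3.csv")
    state["trajectory"] = traj
    state["association"] = assoc
    state["patterns6"] = pats6
    report["trajectory"] = {
        "n_lineages": len(traj.lineages),
        "lineages": [list(l) for l in traj.lineages],
        "n_trajectory_genes": len(traj_genes),
        "n_tested_genes": len(assoc_genes),
        "n_significant_genes": len(sig_genes),
        "pattern6_sizes": pats6.groups.value_counts().to_dict(),
        "pattern3_sizes": pats3.groups.value_counts().to_dict(),
    }


def _stage_transfer(cfg, state, report, outdir):
    norm = state["norm"]
    if cfg.transfer_query_dir:
        query_raw = lio.read_bundle(cfg.transfer_query_dir)
    else:
        sim2 = dataclasses.replace(cfg.sim, seed=cfg.sim.seed + 1)
        query_raw = simulate_dataset(sim2)
    q1 = lqc.basic_gene_cell_filter(query_raw, cfg.qc)
    q2 = lqc.qc_cell_filter(q1, cfg.qc)
    q3 = lqc.contaminant_filter(q2, cfg.qc.contaminant_rules)
    query = lqc.log_normalize(q3)
    res = ltrans.transfer_labels(norm, norm.obs["cluster"], query,
                                 k=cfg.transfer_k)
    qlab = query.obs["stage"].astype(str) if "stage" in query.obs \
        else pd.Series("all", index=query.obs_names)
    flow = ltrans.flow_table(qlab, res.predicted)
    res.scores.to_csv(outdir / "transfer_scores.csv")
    flow.to_csv(outdir / "transfer_flow.csv", index=False)
    if "stage" in query.obs and "stage" in norm.obs:
        # a reference cluster stands for its majority truth stage
        mapping = pd.crosstab(norm.obs["cluster"],
                              norm.obs["stage"]).idxmax(axis=1)
        mapped = res.predicted.map(mapping.astype(str).to_dict()).to_numpy()
        agree = float((mapped == qlab.to_numpy()).mean())
    else:
        agree = None
    report["transfer"] = {
        "n_query_cells": int(query.n_obs),
        "flow": flow.to_dict(orient="records"),
        "agreement_with_truth_stage": agree,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "cluster": _stage_cluster,
    "score": _stage_score,
    "regulons": _stage_regulons,
    "trajectory": _stage_trajectory,
    "transfer": _stage_transfer,
}
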