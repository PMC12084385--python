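"""Reading and writing the pipeline's on-disk formats.

Count matrices travel as Matrix Market (genes × cells, 1-based indices)
plus ``genes.tsv`` / ``cells.tsv`` sidecars; ground truth as JSON (regulons,
config) with the per-cell/per-gene truth columns living in the TSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy.sparse import csr_matrix

__all__ = ["write_bundle", "read_bundle", "read_signature", "write_signature"]


def write_bundle(adata: ad.AnnData, outdir) -> Path:
    """Write counts (MTX, genes × cells), gene/cell tables and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.layers["counts"] if "counts" in adata.layers else adata.X
    spio.mmwrite(str(outdir / "matrix.mtx"), csr_matrix(np.asarray(X).T))
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")
    truth = {}
    if "regulons" in adata.uns:
        truth["regulons"] = {tf: list(t) for tf, t in
                             adata.uns["regulons"].items()}
    if "sim_config" in adata.uns:
        truth["sim_config"] = {k: (v.tolist() if isinstance(v, np.ndarray)
                                   else v)
                               for k, v in adata.uns["sim_config"].items()}
    if truth:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    if "true_regulon_activity" in adata.obsm:
        pd.DataFrame(adata.obsm["true_regulon_activity"],
                     index=adata.obs_names) \
            .to_csv(outdir / "true_regulon_activity.tsv", sep="\t")
    return outdir


def read_bundle(indir) -> ad.AnnData:
    """Read a bundle written by :func:`write_bundle` back into AnnData."""
    indir = Path(indir)
    M = spio.mmread(str(indir / "matrix.mtx")).tocsr().T.toarray()
    var = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    adata = ad.AnnData(X=M.astype(np.int64), obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    truth_path = indir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
        for key, value in truth.items():
            adata.uns[key] = value
    act_path = indir / "true_regulon_activity.tsv"
    if act_path.exists():
        adata.obsm["true_regulon_activity"] = pd.read_csv(
            act_path, sep="\t", index_col=0)
    return adata


def read_signature(path) -> list:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def write_signature(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + "\n")
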