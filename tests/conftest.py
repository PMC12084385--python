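"""Shared fixtures: all inputs are generated programmatically at test time."""

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import lumipath as lp
from lumipath import qc as lqc
from lumipath import trajectory as ltraj
from lumipath.cluster import cluster_cells, integrate_batches, name_clusters


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic lineage-conversion bundle (500 cells, seed 7)."""
    return lp.simulate_dataset(lp.SimConfig(seed=7))


@pytest.fixture(scope="session")
def norm(bundle):
    """QC-filtered, log-normalized default bundle."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        step = lqc.basic_gene_cell_filter(bundle)
        step = lqc.qc_cell_filter(step)
        step = lqc.contaminant_filter(step)
        return lqc.log_normalize(step)


@pytest.fixture(scope="session")
def analysis(norm):
    """The full default analysis chain on the synthetic bundle: integrated
    embedding, named clusters, trajectories and association results."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hvg = lqc.select_hvg(norm, 2000)
        scaled = lqc.scale_features(norm, hvg)
        emb = integrate_batches(scaled, norm.obs["batch"].astype(str).to_numpy(),
                                "batch1")
        labels = cluster_cells(emb, resolution=0.5, seed=0)
        named, naming_info = name_clusters(norm, labels,
                                           facs=norm.obs["facs_gate"])
        traj = ltraj.fit_trajectory(emb, named, "BAS")
        pt = traj.pseudotime["lineage1"]
        cells = pt.index[pt.notna()]
        counts = pd.DataFrame(np.asarray(norm[cells].layers["counts"]),
                              index=cells, columns=norm.var_names)
        traj_genes = set(ltraj.filter_trajectory_genes(counts))
        hvg4k = lqc.select_hvg(norm.copy(), n=min(4000, norm.n_vars))
        genes = [g for g in hvg4k if g in traj_genes]
        expr = pd.DataFrame(np.asarray(norm[cells, genes].X),
                            index=cells, columns=genes)
        assoc = ltraj.association_test(expr, pt.loc[cells], n_knots=8)
    return {
        "norm": norm, "embedding": emb, "labels": labels, "named": named,
        "naming_info": naming_info, "trajectory": traj, "pseudotime": pt,
        "cells": cells, "expr": expr, "assoc": assoc,
    }


def toy_adata(counts, genes=None, cells=None):
    """Small dense AnnData from an integer array."""
    counts = np.asarray(counts, dtype=np.int64)
    n, g = counts.shape
    genes = list(genes) if genes is not None else [f"g{j}" for j in range(g)]
    cells = list(cells) if cells is not None else [f"c{i}" for i in range(n)]
    adata = ad.AnnData(X=counts,
                       obs=pd.DataFrame(index=cells),
                       var=pd.DataFrame(index=genes))
    adata.layers["counts"] = counts.copy()
    return adata


def toy_norm(values, genes=None, cells=None):
    """AnnData whose .X already holds log-normalized values (float)."""
    values = np.asarray(values, dtype=float)
    adata = toy_adata(np.zeros_like(values, dtype=np.int64), genes, cells)
    adata.X = values
    return adata
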