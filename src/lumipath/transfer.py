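"""Cross-dataset label transfer and alluvial flow tables.

The reference dataset's highly variable genes define a PCA space (fitted on
the reference); query cells are projected with the reference loadings after
matching per-gene centering/scaling, and each query cell receives a
Gaussian-kernel-weighted k-nearest-neighbor vote over reference labels.
The per-cell score vector sums to 1 and the predicted ID is its argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import qc
from .cluster import run_pca

__all__ = ["TransferResult", "transfer_labels", "flow_table"]


@dataclass
class TransferResult:
    predicted: pd.Series                # query cell → reference label
    scores: pd.DataFrame                # query cells × reference labels
    ties: pd.Series                     # flagged argmax ties


def transfer_labels(reference, ref_labels, query, n_pcs: int = 30,
                    k: int = 30, n_hvg: int = 2000) -> TransferResult:
    """Transfer reference cluster labels onto query cells.

    ``reference`` and ``query`` are log-normalized AnnData objects (raw
    counts in ``layers["counts"]``).  Requires >= 100 shared genes.  The
    kernel bandwidth per query cell is a third of its k-th neighbor
    distance, so a zero-distance neighbor (self-transfer) dominates the
    vote.  Ties at the argmax go to the alphabetically first label and are
    flagged.
    """
    ref_labels = pd.Series(np.asarray(ref_labels, dtype=object),
                           index=reference.obs_names)
    shared = reference.var_names.intersection(query.var_names)
    if len(shared) < 100:
        raise ValueError(f"only {len(shared)} shared genes; need >= 100")
    ref = reference[:, shared]
    hvg = qc.select_hvg(ref.copy(), n=min(n_hvg, len(shared)))
    Xr = np.asarray(ref[:, hvg].X, dtype=float)
    Xq = np.asarray(query[:, hvg].X, dtype=float)
    mean = Xr.mean(axis=0)
    sd = Xr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Zr = np.minimum((Xr - mean) / sd, 10.0)
    Zq = np.minimum((Xq - mean) / sd, 10.0)
    pca = run_pca(pd.DataFrame(Zr, index=ref.obs_names, columns=hvg),
                  n_components=min(n_pcs, min(Zr.shape)))
    Er = pca.scores.to_numpy()
    Eq = (Zq - pca.mean) @ pca.components.T

    k = min(k, Er.shape[0])
    tree = cKDTree(Er)
    dists, idx = tree.query(Eq, k=k)
    dists = np.atleast_2d(dists)
    idx = np.atleast_2d(idx)
    label_values = sorted(ref_labels.unique())
    lab_codes = ref_labels.map({l: i for i, l in enumerate(label_values)}) \
        .to_numpy()
    sigma = dists[:, -1] / 3.0
    scores = np.zeros((Eq.shape[0], len(label_values)))
    for i in range(Eq.shape[0]):
        if sigma[i] <= 0:                      # all neighbors coincident
            w = (dists[i] == 0).astype(float)
        else:
            w = np.exp(-(dists[i] / sigma[i]) ** 2)
        np.add.at(scores[i], lab_codes[idx[i]], w)
    totals = scores.sum(axis=1, keepdims=True)
    scores = scores / np.maximum(totals, 1e-300)
    best = scores.argmax(axis=1)
    top = scores.max(axis=1)
    n_at_top = (np.isclose(scores, top[:, None])).sum(axis=1)
    ties = pd.Series(n_at_top > 1, index=query.obs_names)
    predicted = pd.Series([label_values[b] for b in best],
                          index=query.obs_names)
    return TransferResult(
        predicted=predicted,
        scores=pd.DataFrame(scores, index=query.obs_names,
                            columns=label_values),
        ties=ties)


def flow_table(query_labels, predicted_ids) -> pd.DataFrame:
    """Contingency flow counts per (query cluster, predicted ID) pair, in
    long form for alluvial plotting; marginals equal the cluster sizes."""
    q = pd.Series(np.asarray(query_labels, dtype=object), name="query_cluster")
    p = pd.Series(np.asarray(predicted_ids, dtype=object), name="predicted_id")
    if len(q) != len(p):
        raise ValueError("label vectors have different lengths")
    tab = pd.crosstab(q, p)
    long = tab.stack().rename("n_cells").reset_index()
    return long[long["n_cells"] > 0].reset_index(drop=True)
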