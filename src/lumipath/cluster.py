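"""PCA, batch integration, SNN graph clustering, subclustering and UMAP.

Clustering follows the Smart-seq2 pipeline conventions: a shared-nearest-
neighbor graph (k=20, Jaccard-weighted, pruned at 1/15) over the first 30
principal components, partitioned with the Leiden algorithm at the study's
resolutions (0.5 globally, 0.6 for targeted subclustering), and a seeded
UMAP with spread 0.4.  Batch integration is a locally smoothed mutual-
nearest-neighbor (MNN) shift toward a designated reference batch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "run_pca",
    "integrate_batches",
    "snn_graph",
    "cluster_cells",
    "subcluster",
    "run_umap",
    "name_clusters",
    "BASAL_MARKERS",
    "LUMINAL_MARKERS",
    "HR_MARKERS",
]

BASAL_MARKERS = ("Krt5", "Krt14", "Acta2")
LUMINAL_MARKERS = ("Krt8", "Krt19")
HR_MARKERS = ("Esr1", "Pgr")


@dataclass
class PCAResult:
    scores: pd.DataFrame              # cells × components
    explained_variance_ratio: np.ndarray
    components: np.ndarray            # components × genes (loadings)
    mean: np.ndarray
    genes: list


def run_pca(scaled: pd.DataFrame, n_components: int = 30) -> PCAResult:
    """PCA with deterministic sign convention (the largest-magnitude loading
    of each component is positive); components ordered by explained variance.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(scaled, dtype=float)
    max_rank = min(X.shape)
    if n_components > max_rank:
        warnings.warn(f"requested {n_components} components but rank is at most "
                      f"{max_rank}; reducing")
        n_components = max_rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps = pca.components_
    # effective rank may still be lower than requested
    nonzero = pca.explained_variance_ > 1e-12
    if not nonzero.all():
        warnings.warn(f"input rank {nonzero.sum()} < {n_components} components")
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] *= -1
            scores[:, i] *= -1
    idx = getattr(scaled, "index", pd.RangeIndex(X.shape[0]))
    cols = [f"PC{i + 1}" for i in range(comps.shape[0])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=comps,
        mean=pca.mean_,
        genes=list(getattr(scaled, "columns", range(X.shape[1]))),
    )


def integrate_batches(scaled: pd.DataFrame, batches, reference,
                      n_pcs: int = 30, k_mnn: int = 20,
                      sigma_quantile: float = 0.5) -> pd.DataFrame:
    """Smoothed mutual-nearest-neighbor correction in joint PCA space.

    PCA is fitted on all cells; for each non-reference batch, MNN pairs with
    the reference define correction vectors (reference minus query), which
    are smoothed over the batch with a Gaussian kernel (bandwidth = the
    ``sigma_quantile`` quantile of pairwise anchor distances) and added to
    the batch's embedding.  Within-batch geometry is preserved up to this
    smooth shift; batches with no MNN pairs are left uncorrected.
    """
    batches = np.asarray(batches)
    if reference not in batches:
        raise ValueError(f"reference batch {reference!r} not present")
    pca = run_pca(scaled, n_components=n_pcs)
    emb = pca.scores.to_numpy().copy()
    ref_idx = np.flatnonzero(batches == reference)
    ref_emb = emb[ref_idx]
    ref_tree = cKDTree(ref_emb)
    for b in np.unique(batches):
        if b == reference:
            continue
        q_idx = np.flatnonzero(batches == b)
        q_emb = emb[q_idx]
        k = min(k_mnn, len(ref_idx), len(q_idx))
        _, ref_nn = ref_tree.query(q_emb, k=k)        # query → reference
        q_tree = cKDTree(q_emb)
        _, q_nn = q_tree.query(ref_emb, k=k)          # reference → query
        ref_nn = np.atleast_2d(ref_nn)
        q_nn = np.atleast_2d(q_nn)
        fwd = {(qi, rj) for qi in range(len(q_idx)) for rj in ref_nn[qi]}
        pairs = [(qi, rj) for rj in range(len(ref_idx)) for qi in q_nn[rj]
                 if (qi, rj) in fwd]
        if not pairs:
            warnings.warn(f"no MNN pairs for batch {b!r}; left uncorrected")
            continue
        qi = np.array([p[0] for p in pairs])
        rj = np.array([p[1] for p in pairs])
        vectors = ref_emb[rj] - q_emb[qi]
        anchors = q_emb[qi]
        d_anchor = cKDTree(anchors).query(q_emb, k=1)[0]
        sigma = np.quantile(
            np.linalg.norm(anchors - anchors.mean(axis=0), axis=1), sigma_quantile)
        sigma = max(sigma, 1e-8)
        # Gaussian-kernel smoothing of pair vectors over all batch cells
        d2 = ((q_emb[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 / (2.0 * sigma ** 2))
        w_sum = w.sum(axis=1, keepdims=True)
        w = np.where(w_sum > 0, w / np.maximum(w_sum, 1e-300), 0.0)
        correction = w @ vectors
        # cells far from every anchor fall back to the mean correction
        far = w_sum.ravel() <= 1e-300
        if far.any():
            correction[far] = vectors.mean(axis=0)
        emb[q_idx] = q_emb + correction
        logger.info("batch %s: %d MNN pairs, mean |shift| %.3f (d_anchor med %.3f)",
                    b, len(pairs), np.linalg.norm(correction, axis=1).mean(),
                    np.median(d_anchor))
    return pd.DataFrame(emb, index=pca.scores.index, columns=pca.scores.columns)


def snn_graph(embedding, k_neighbors: int = 20, prune: float = 1 / 15):
    """Jaccard-weighted shared-nearest-neighbor graph.

    Neighbor sets of size ``k_neighbors`` include the cell itself; edge
    weight = |shared| / |union| of the two neighbor sets, pruned below
    ``prune``.  Returns a symmetric sparse matrix.
    """
    from sklearn.neighbors import NearestNeighbors

    X = np.asarray(embedding, dtype=float)
    n = X.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < n_cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(X)
    idx = nn.kneighbors(return_distance=False)
    rows = np.repeat(np.arange(n), k_neighbors - 1)
    cols = idx[:, : k_neighbors - 1].ravel()
    # adjacency of neighbor sets including self
    A = csr_matrix((np.ones(len(rows) + n),
                    (np.concatenate([rows, np.arange(n)]),
                     np.concatenate([cols, np.arange(n)]))),
                   shape=(n, n))
    A.data[:] = 1.0
    shared = (A @ A.T).tocoo()
    jac_rows, jac_cols = shared.row, shared.col
    union = 2 * k_neighbors - shared.data
    jac = shared.data / union
    keep = (jac >= prune) & (jac_rows != jac_cols)
    return csr_matrix((jac[keep], (jac_rows[keep], jac_cols[keep])), shape=(n, n))


def _leiden(graph, resolution: float, seed: int) -> np.ndarray:
    import igraph as ig
    import leidenalg

    coo = graph.tocoo()
    mask = coo.row < coo.col
    edges = list(zip(coo.row[mask], coo.col[mask]))
    weights = coo.data[mask].tolist()
    g = ig.Graph(n=graph.shape[0], edges=edges)
    if g.components().__len__() > 1:
        warnings.warn("SNN graph is disconnected; clustering each component")
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=weights, resolution_parameter=resolution, seed=int(seed),
        n_iterations=-1)
    return np.asarray(part.membership)


def cluster_cells(embedding, resolution: float = 0.5, k_neighbors: int = 20,
                  seed: int = 0, prune: float = 1 / 15) -> pd.Series:
    """Leiden community detection on the SNN graph; labels are strings
    ("0", "1", ...) sorted by decreasing cluster size, deterministic given
    the seed."""
    graph = snn_graph(embedding, k_neighbors=k_neighbors, prune=prune)
    membership = _leiden(graph, resolution, seed)
    sizes = pd.Series(membership).value_counts()
    # stable relabeling: by size, ties by first occurrence
    order = sorted(sizes.index, key=lambda c: (-sizes[c], c))
    remap = {old: str(new) for new, old in enumerate(order)}
    labels = pd.Series([remap[m] for m in membership],
                       index=getattr(embedding, "index", None), dtype=object)
    logger.info("clustering: %d clusters at resolution %.2f",
                labels.nunique(), resolution)
    return labels


def subcluster(embedding, labels: pd.Series, target: str,
               resolution: float = 0.6, k_neighbors: int = 20,
               seed: int = 0) -> pd.Series:
    """Re-cluster the cells of ``target`` on their own SNN graph; other
    labels are untouched and new labels are suffixed ``target_0``, ..."""
    labels = pd.Series(labels, dtype=object)
    mask = (labels == target).to_numpy()
    if not mask.any():
        raise ValueError(f"target label {target!r} not present")
    if mask.sum() < k_neighbors + 1:
        raise ValueError(
            f"subset of {mask.sum()} cells too small for k={k_neighbors}")
    sub_emb = np.asarray(embedding, dtype=float)[mask]
    sub = cluster_cells(sub_emb, resolution=resolution,
                        k_neighbors=k_neighbors, seed=seed)
    out = labels.copy()
    out.iloc[np.flatnonzero(mask)] = [f"{target}_{s}" for s in sub]
    return out


def run_umap(embedding, spread: float = 0.4, min_dist: float = 0.3,
             n_neighbors: int = 15, seed: int = 0) -> pd.DataFrame:
    """Seeded 2-D UMAP of the PCA embedding (spread 0.4 per the pipeline)."""
    import umap

    X = np.asarray(embedding, dtype=float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 cells for UMAP")
    reducer = umap.UMAP(n_components=2, spread=spread, min_dist=min_dist,
                        n_neighbors=n_neighbors, random_state=int(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(X)
    return pd.DataFrame(coords, index=getattr(embedding, "index", None),
                        columns=["UMAP1", "UMAP2"])


def name_clusters(norm, labels: pd.Series, facs=None) -> tuple[pd.Series, dict]:
    """Assign the study's cluster vocabulary {BAS, INT1, INT2, HRneg, HRpos}.

    Per-cluster mean expression of canonical basal (Krt5/Krt14/Acta2),
    luminal (Krt8/Krt19) and hormone-receptor (Esr1/Pgr) markers is computed
    on the normalized matrix.  The cluster with the highest HR score becomes
    HRpos; the remaining clusters are ordered by (luminal − basal) score:
    the most basal is BAS, the most luminal HRneg, and interior clusters
    INT1, INT2, ... from basal to luminal.  FACS gate composition, when
    provided, is reported in the returned mapping for inspection.
    """
    labels = pd.Series(labels, dtype=object)
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to name")

    def score(markers):
        present = [g for g in markers if g in norm.var_names]
        if not present:
            return pd.Series(0.0, index=clusters)
        X = np.asarray(norm[:, present].X, dtype=float).mean(axis=1)
        return pd.Series(X).groupby(labels.to_numpy()).mean().reindex(clusters)

    bas = score(BASAL_MARKERS)
    lum = score(LUMINAL_MARKERS)
    hr = score(HR_MARKERS)
    mapping = {}
    hr_cluster = hr.idxmax()
    mapping[hr_cluster] = "HRpos"
    rest = [c for c in clusters if c != hr_cluster]
    polarity = (lum - bas).loc[rest].sort_values()
    ordered = list(polarity.index)
    names = {}
    names[ordered[0]] = "BAS"
    names[ordered[-1]] = "HRneg"
    for i, c in enumerate(ordered[1:-1]):
        names[c] = f"INT{i + 1}"
    mapping.update(names)
    info = {"basal_score": bas.to_dict(), "luminal_score": lum.to_dict(),
            "hr_score": hr.to_dict(), "mapping": dict(mapping)}
    if facs is not None:
        info["facs_composition"] = {
            c: pd.Series(np.asarray(facs)[labels.to_numpy() == c])
                 .value_counts(normalize=True).to_dict()
            for c in clusters}
    named = labels.map(mapping)
    return named, info
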