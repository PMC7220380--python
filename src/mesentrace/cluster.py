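"""Dimensionality reduction, graph clustering, 2-D embedding, marker detection.

The clustering contract is the standard single-cell stack: PCA on scaled
expression of the selected genes, a shared-nearest-neighbor (SNN) graph in
PC space with Jaccard edge weights, and modularity community detection
(Leiden, delegated to python-igraph / leidenalg). Cluster markers come from
a two-sided Wilcoxon rank-sum test of each cluster against all remaining
cells with Benjamini-Hochberg correction across genes.

The 2-D embeddings (tSNE / UMAP) are for visualization only; trajectory
inference consumes the PC space directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .qc import NormalizedMatrix

__all__ = ["ClusterAssignment", "MarkerTable", "pca", "cluster_cells", "embed_2d", "find_markers"]


@dataclass
class ClusterAssignment:
    """Per-cell cluster labels (small integers) plus cluster sizes."""

    labels: pd.Series  # index = cell ids, values = int cluster ids

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def cluster_ids(self) -> list[int]:
        return sorted(self.labels.unique())


@dataclass
class MarkerTable:
    """Rank-sum marker results for one cluster vs the rest.

    Columns: gene_id, log_fc, auc, p_value, p_adj.
    """

    table: pd.DataFrame
    cluster: int


def pca(norm: NormalizedMatrix, genes: list[str] | None = None, n_pcs: int = 30) -> np.ndarray:
    """Cells x n_pcs principal components of centered, unit-scaled gene expression.

    Components are ordered by decreasing explained variance. Zero-variance
    genes are centered but not scaled.
    """
    if genes is None:
        genes = list(norm.gene_ids)
    missing = set(genes) - set(norm.gene_ids)
    if missing:
        raise ValueError(f"genes absent from the matrix: {sorted(missing)[:5]}")
    idx = norm.gene_ids.get_indexer(genes)
    X = norm.values[idx, :].T  # cells x genes
    if n_pcs >= min(X.shape):
        raise ValueError(f"n_pcs = {n_pcs} must be < min(n_cells, n_genes) = {min(X.shape)}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    model = PCA(n_components=n_pcs, svd_solver="full")
    return model.fit_transform(Xs)


def _snn_graph(pcs: np.ndarray, k_neighbors: int) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard weights over kNN pairs."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(pcs)
    knn = nn.kneighbors_graph(pcs, mode="connectivity")  # includes self at k>=1? no: excludes
    # include each cell in its own neighborhood, as Seurat does
    knn = knn + sp.identity(n, format="csr")
    knn.data[:] = 1.0
    shared = knn @ knn.T  # number of shared neighbors
    shared = sp.triu(shared.tocoo(), k=1)
    kk = k_neighbors + 1
    jaccard = shared.data / (2 * kk - shared.data)
    keep = jaccard >= 1.0 / 15.0  # Seurat's default pruning threshold
    edges = list(zip(shared.row[keep].tolist(), shared.col[keep].tolist()))
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def cluster_cells(
    pcs: np.ndarray,
    cell_ids: pd.Index | None = None,
    k_neighbors: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Leiden modularity clustering on the SNN graph of the PC space.

    Deterministic under a fixed seed; singleton clusters are permitted.
    """
    n = pcs.shape[0]
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    if n <= k_neighbors:
        raise ValueError(f"need more cells ({n}) than k_neighbors ({k_neighbors})")
    g = _snn_graph(np.asarray(pcs, dtype=float), k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership, dtype=int)
    if cell_ids is None:
        cell_ids = pd.RangeIndex(n)
    return ClusterAssignment(pd.Series(labels, index=pd.Index(cell_ids), name="cluster"))


def embed_2d(pcs: np.ndarray, method: str = "umap", seed: int = 0) -> np.ndarray:
    """2-D embedding of the PC space for plotting (never for inference)."""
    pcs = np.asarray(pcs, dtype=float)
    if method == "umap":
        import umap

        reducer = umap.UMAP(n_components=2, random_state=seed)
        return np.asarray(reducer.fit_transform(pcs), dtype=float)
    if method == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (pcs.shape[0] - 1) / 3.0))
        reducer = TSNE(n_components=2, random_state=seed, init="pca", perplexity=perplexity)
        return np.asarray(reducer.fit_transform(pcs), dtype=float)
    raise ValueError(f"unknown embedding method {method!r}; use 'umap' or 'tsne'")


def find_markers(
    norm: NormalizedMatrix, clusters: ClusterAssignment, target_cluster: int
) -> MarkerTable:
    """Markers of one cluster vs all remaining cells.

    Per gene: two-sided Wilcoxon rank-sum p-value, AUC (probability a
    target cell exceeds a non-target cell, ties counted half), and
    log fold-change ln((m1 + 1) / (m2 + 1)) of depth-scaled means; BH
    adjustment across genes.
    """
    labels = clusters.labels.reindex(norm.cell_ids)
    if labels.isna().any():
        raise ValueError("cluster assignment does not cover all cells in the matrix")
    in_target = (labels == target_cluster).to_numpy()
    n1, n2 = int(in_target.sum()), int((~in_target).sum())
    if target_cluster not in set(clusters.labels.unique()):
        raise ValueError(f"cluster {target_cluster} not present")
    if n1 < 3:
        raise ValueError(f"cluster {target_cluster} has fewer than 3 cells")

    X1 = norm.values[:, in_target]
    X2 = norm.values[:, ~in_target]
    res = stats.mannwhitneyu(X1, X2, axis=1, alternative="two-sided", method="asymptotic")
    auc = res.statistic / (n1 * n2)
    # constant genes: mannwhitneyu's normal approximation degenerates; force p = 1
    constant = (np.ptp(X1, axis=1) == 0) & (np.ptp(X2, axis=1) == 0)
    constant &= X1[:, 0] == X2[:, 0]
    pvals = np.where(constant, 1.0, res.pvalue)
    m1 = np.expm1(X1).mean(axis=1)
    m2 = np.expm1(X2).mean(axis=1)
    log_fc = np.log(m1 + 1.0) - np.log(m2 + 1.0)
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "gene_id": norm.gene_ids,
            "log_fc": log_fc,
            "auc": auc,
            "p_value": pvals,
            "p_adj": p_adj,
        }
    ).sort_values("p_adj", kind="stable").reset_index(drop=True)
    return MarkerTable(table, cluster=int(target_cluster))
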