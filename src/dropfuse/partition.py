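"""Cell clustering and block partitioning of the expression matrix.

Cells are embedded with PCA on the top-ranked gene group, clustered with
spectral clustering on a symmetrized k-nearest-neighbor affinity graph, and
the cluster count k is selected by the mean silhouette over a search range.
The expression matrix is then tiled into gene-group x cell-cluster blocks,
the unit at which similarities and latent features are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from sklearn.neighbors import kneighbors_graph

from .io import ExpressionMatrix, GeneGrouping


@dataclass
class ClusterAssignment:
    """Cell cluster labels in 0..k-1 with the mean silhouette in PCA space."""

    labels: np.ndarray
    k: int
    silhouette: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError(
                f"labels must cover 0..{self.k - 1}; found {present.tolist()}")

    def to_frame(self, cell_ids):
        """Two-column (cell_id, label) table for CSV export."""
        import pandas as pd
        return pd.DataFrame({"cell_id": list(cell_ids),
                             "label": self.labels})


@dataclass
class KSelection:
    """Silhouette scores over the searched k range and the selected values."""

    scores: dict[int, float]
    best_k: int
    top3_k: tuple[int, ...]
    assignments: dict[int, ClusterAssignment]


@dataclass
class Block:
    """One gene-group x cell-cluster view with index maps into the full matrix."""

    group: int
    cluster: int
    gene_idx: np.ndarray
    cell_idx: np.ndarray
    values: np.ndarray


@dataclass
class BlockPartition:
    """Tiling of the full matrix into r x k blocks."""

    blocks: dict[tuple[int, int], Block]
    r: int
    k: int
    shape: tuple[int, int]

    def reassemble(self) -> np.ndarray:
        out = np.empty(self.shape)
        out.fill(np.nan)
        for b in self.blocks.values():
            out[np.ix_(b.gene_idx, b.cell_idx)] = b.values
        return out


def pca_embed(M: np.ndarray, n_components: int = 50,
              seed: int = 0) -> np.ndarray:
    """Centered PCA of cells (columns of the genes x cells matrix M).

    Returns a cells x d embedding with d = min(n_components, cells - 1,
    genes).  A full SVD solver keeps the result deterministic.
    """
    M = np.asarray(M, dtype=float)
    n_genes, n_cells = M.shape
    if n_cells < 3:
        raise ValueError("PCA embedding needs at least 3 cells")
    d = min(n_components, n_cells - 1, n_genes)
    pca = PCA(n_components=d, svd_solver="full", random_state=seed)
    return pca.fit_transform(M.T)


def _knn_affinity(E: np.ndarray, n_neighbors: int) -> np.ndarray:
    n = E.shape[0]
    n_neighbors = min(n_neighbors, n - 1)
    A = kneighbors_graph(E, n_neighbors=n_neighbors, mode="connectivity")
    W = 0.5 * (A + A.T).toarray()
    n_comp, _ = connected_components(W > 0, directed=False)
    if n_comp > 1:
        warnings.warn(
            f"kNN affinity graph has {n_comp} components; "
            "adding epsilon affinity to connect them")
        W = W + 1e-8
        np.fill_diagonal(W, 0.0)
    return W


def spectral_cluster(E: np.ndarray, k: int, seed: int = 0,
                     n_neighbors: int = 15) -> ClusterAssignment:
    """Spectral clustering of an embedding on a symmetrized kNN graph.

    The k-means step is seeded, so results are reproducible for a fixed
    seed.  The silhouette is computed in the embedding with Euclidean
    distance.
    """
    E = np.asarray(E, dtype=float)
    n = E.shape[0]
    if k < 2 or k >= n:
        raise ValueError(f"need 2 <= k < n_cells; got k={k}, n={n}")
    W = _knn_affinity(E, n_neighbors)
    sc = SpectralClustering(
        n_clusters=k, affinity="precomputed", random_state=seed,
        assign_labels="kmeans")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = sc.fit_predict(W)
    # relabel to a dense 0..k'-1 range (k-means may leave a cluster empty)
    _, labels = np.unique(raw, return_inverse=True)
    k_eff = labels.max() + 1
    sil = float(silhouette_score(E, labels, metric="euclidean"))
    return ClusterAssignment(labels=labels, k=int(k_eff), silhouette=sil)


def select_k(E: np.ndarray, k_range=range(4, 16), seed: int = 0,
             n_neighbors: int = 15) -> KSelection:
    """Run spectral clustering over a k range and select by mean silhouette.

    Ties break toward smaller k.  Returns the best k, the three
    highest-scoring distinct k values (fewer if the range is shorter), and
    all assignments for reuse.
    """
    ks = [int(k) for k in k_range]
    if not ks:
        raise ValueError("empty k range")
    n = np.asarray(E).shape[0]
    scores: dict[int, float] = {}
    assignments: dict[int, ClusterAssignment] = {}
    for k in ks:
        if k >= n:
            warnings.warn(f"skipping infeasible k={k} (only {n} cells)")
            continue
        ca = spectral_cluster(E, k, seed=seed, n_neighbors=n_neighbors)
        scores[k] = ca.silhouette
        assignments[k] = ca
    if not scores:
        raise ValueError("no feasible k in the searched range")
    ordered = sorted(scores, key=lambda k: (-scores[k], k))
    return KSelection(scores=scores, best_k=ordered[0],
                      top3_k=tuple(ordered[:3]), assignments=assignments)


def partition_matrix(X: ExpressionMatrix, grouping: GeneGrouping,
                     clusters: ClusterAssignment) -> BlockPartition:
    """Tile the matrix into gene-group x cell-cluster blocks.

    Block (g, c) holds the rows of group g and the columns of cluster c;
    the index maps make the tiling invertible.
    """
    blocks: dict[tuple[int, int], Block] = {}
    cell_idx_by_cluster = [
        np.flatnonzero(clusters.labels == c) for c in range(clusters.k)]
    for g, genes in enumerate(grouping.group_assignments):
        gidx = np.asarray(genes, dtype=int)
        for c, cidx in enumerate(cell_idx_by_cluster):
            blocks[(g, c)] = Block(
                group=g, cluster=c, gene_idx=gidx, cell_idx=cidx,
                values=X.values[np.ix_(gidx, cidx)])
    return BlockPartition(blocks=blocks, r=grouping.r, k=clusters.k,
                          shape=X.values.shape)
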