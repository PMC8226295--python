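"""KNN-graph community clustering of the PCA embedding."""
from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterAssignment:
    """Per-cell community labels, 0-based and ordered by decreasing size."""

    labels: np.ndarray
    resolution: float
    k_neighbors: int

    @property
    def n_clusters(self):
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def knn_graph(embedding: np.ndarray, k: int = 20, prune: float = SNN_PRUNE) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph over cells in PC space.

    Each cell is linked to its k Euclidean neighbors; edge weights are
    the Jaccard overlap of the two cells' (self-inclusive) neighbor
    sets, and edges with overlap below `prune` are removed. The result
    is symmetric with a zero diagonal and is deterministic given the
    embedding (neighbor ties break by cell index).
    """
    x = np.asarray(embedding, dtype=np.float64)
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    _, idx = nn.kneighbors(x)
    rows = np.repeat(np.arange(n), k + 1)
    adj = sp.csr_matrix(
        (np.ones(idx.size), (rows, idx.ravel())), shape=(n, n)
    )
    shared = (adj @ adj.T).tocoo()
    size = float(k + 1)
    jac = shared.data / (2 * size - shared.data)
    keep = (jac >= prune) & (shared.row != shared.col)
    g = sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    return g


def cluster_graph(graph: sp.spmatrix, resolution: float = 0.5, seed: int = 0) -> ClusterAssignment:
    """Leiden community detection (RB modularity with resolution).

    Labels are relabelled by decreasing community size (ties by first
    occurrence); deterministic for a fixed graph and seed.
    """
    g = sp.coo_matrix(graph)
    upper = g.row < g.col
    edges = list(zip(g.row[upper].tolist(), g.col[upper].tolist()))
    weights = g.data[upper].tolist()
    graph_ig = ig.Graph(n=g.shape[0], edges=edges)
    part = leidenalg.find_partition(
        graph_ig,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights or None,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    labels = _relabel_by_size(raw)
    return ClusterAssignment(labels=labels, resolution=resolution, k_neighbors=-1)


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    ids, counts = np.unique(raw, return_counts=True)
    order = np.lexsort((ids, -counts))
    mapping = np.empty(ids.max() + 1, dtype=np.int64)
    mapping[ids[order]] = np.arange(len(ids))
    return mapping[raw]
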