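"""Spatial neighbor graph construction and GCN-style normalization.

Each spot is connected to its k nearest Euclidean neighbors; the directed
relation is symmetrized by union, so every spot ends up with at least k
neighbors.  The encoder consumes the symmetric renormalized adjacency
A_hat = D^{-1/2} (A + I) D^{-1/2} with self-loops, the standard stabilization
for graph convolutions.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .types import SpatialCoordinates, SpatialGraph

logger = logging.getLogger(__name__)


def build_knn_graph(coords: SpatialCoordinates, k: int = 6) -> SpatialGraph:
    """Union-symmetrized k-nearest-neighbor graph on spot coordinates.

    Distance ties are broken by lower spot index so the adjacency is
    deterministic; duplicate coordinates are allowed but logged.
    """
    n = coords.n_spots
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots {n}")

    pos = coords.positions
    uniq = np.unique(pos, axis=0)
    if uniq.shape[0] < n:
        logger.warning("%d duplicate coordinate rows; neighbor ties broken "
                       "by spot index", n - uniq.shape[0])

    # Query k+1 and drop self; sklearn orders by distance, but equal distances
    # need an explicit index tie-break, so re-rank by (distance, index).
    nn = NearestNeighbors(n_neighbors=min(n, k + 2), algorithm="auto")
    nn.fit(pos)
    dist, ind = nn.kneighbors(pos)

    rows, cols = [], []
    for i in range(n):
        cand = [(d, j) for d, j in zip(dist[i], ind[i]) if j != i]
        cand.sort(key=lambda t: (t[0], t[1]))
        for d, j in cand[:k]:
            rows.append(i)
            cols.append(j)

    a = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    a = a.maximum(a.T).tocsr()  # union symmetrization
    a.data[:] = 1.0
    a.setdiag(0)
    a.eliminate_zeros()
    graph = SpatialGraph(adjacency=a, k_neighbors=k)
    return normalize_adjacency(graph)


def normalize_adjacency(graph: SpatialGraph) -> SpatialGraph:
    """Attach A_hat = D^{-1/2} (A + I) D^{-1/2} to the graph."""
    a = graph.adjacency.tocsr().astype(float)
    a_loop = a + sp.eye(a.shape[0], format="csr")
    deg = np.asarray(a_loop.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    graph.normalized_adjacency = (d_inv_sqrt @ a_loop @ d_inv_sqrt).tocsr()
    return graph


def edge_list(graph: SpatialGraph) -> np.ndarray:
    """Undirected edges as an m x 2 integer array (i < j)."""
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    return np.column_stack([coo.row, coo.col])
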