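"""Cosine kNN graph with shared-nearest-neighbor weights, and Louvain communities."""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp

from .datatypes import Embedding


@dataclass
class SNNGraph:
    """Undirected shared-nearest-neighbor graph over cells.

    ``adjacency`` is symmetric with zero diagonal; weights are
    |N(i) ∩ N(j)| / k for pairs connected in the kNN graph, in [0, 1].
    """

    adjacency: sp.csr_matrix
    k: int
    metric: str = "cosine"

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    n_clusters: int
    seed: int
    modularity: float


def _knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Exact k nearest neighbors under cosine distance, excluding self.

    Ties are broken by ascending cell index (achieved by stable argsort of
    the distance matrix), so the graph is deterministic.
    """
    X = np.asarray(coords, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = 1.0
    Xn = X / norms[:, None]
    d = 1.0 - Xn @ Xn.T
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def build_snn_graph(embedding: Embedding, k: int = 30, seed: int = 0) -> SNNGraph:
    """Build the SNN graph: kNN under cosine distance, edge weight = shared
    neighbor count / k, zero-weight edges dropped."""
    n = embedding.n_cells
    if k >= n:
        raise ValueError(f"k={k} must be < number of cells ({n})")
    nbrs = _knn_indices(embedding.coords, k)
    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    A = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    # Shared-neighbor counts |N(i) ∩ N(j)| for every cell pair; pairs with no
    # shared neighbor stay absent (weight 0 dropped), the diagonal is removed.
    W = (A @ A.T).tolil()
    W.setdiag(0)
    W = sp.csr_matrix(W) / k
    W.eliminate_zeros()
    return SNNGraph(adjacency=W, k=k)


def louvain_communities(graph: SNNGraph, seed: int = 0) -> ClusterAssignment:
    """Multilevel (Louvain) modularity optimization on the weighted graph."""
    n = graph.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    g = ig.Graph(
        n=n,
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    ig.set_random_number_generator(random.Random(int(seed)))
    part = g.community_multilevel(weights="weight")
    ig.set_random_number_generator(random)  # restore the default generator
    labels = np.asarray(part.membership, dtype=int)
    # contiguous relabeling by first appearance
    _, labels = np.unique(labels, return_inverse=True)
    mod = modularity_from_labels(graph, labels)
    return ClusterAssignment(
        labels=labels, n_clusters=int(labels.max()) + 1, seed=seed, modularity=mod
    )


def modularity_from_labels(graph: SNNGraph, labels: np.ndarray) -> float:
    """Standard weighted modularity Q = sum_c (e_c/m - (d_c/2m)^2)."""
    A = graph.adjacency
    m2 = A.sum()  # 2m for a symmetric matrix
    if m2 == 0:
        return 0.0
    degrees = np.asarray(A.sum(axis=1)).ravel()
    q = 0.0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        e_in = A[np.ix_(idx, idx)].sum()  # counts both directions
        d_c = degrees[idx].sum()
        q += e_in / m2 - (d_c / m2) ** 2
    return float(q)
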