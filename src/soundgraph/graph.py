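"""k-nearest-neighbour graph construction over embedding vectors.

Edges are stored as ordered ``(source, target)`` pairs with the convention
that a directed k-NN edge ``(v, u)`` means *v is one of u's k nearest
neighbours*: messages flow from v into u.  The in-neighbourhood
``N_u = {v : (v, u) in edges}`` is therefore exactly u's k nearest nodes
before symmetrisation.

Symmetric normalisation ``D^{-1/2} (A + I) D^{-1/2}`` presumes an undirected
adjacency, so graphs are symmetrised (edge-set union with its reverse) by
default; the raw digraph is kept available for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass
class KnnGraph:
    """Edge set over ``n_nodes`` recordings plus derived matrix views."""

    n_nodes: int
    edges: np.ndarray  # (E, 2) int64, (source, target), no self-loops
    k: int
    metric: str = "euclidean"
    symmetrized: bool = False

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_nodes:
                raise ValueError("edge endpoint out of range")
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not allowed in the edge set")
        # canonical order: by (source, target); also drops duplicates
        if self.edges.size:
            uniq = np.unique(self.edges, axis=0)
            order = np.lexsort((uniq[:, 1], uniq[:, 0]))
            self.edges = uniq[order]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency A with ``A[s, t] = 1`` for each edge (s, t)."""
        data = np.ones(self.n_edges)
        return sp.csr_matrix(
            (data, (self.edges[:, 0], self.edges[:, 1])),
            shape=(self.n_nodes, self.n_nodes),
        )

    def in_neighbors(self, u: int) -> np.ndarray:
        """N_u: sources of edges arriving at u, ascending."""
        return np.sort(self.edges[self.edges[:, 1] == u, 0])

    def edge_arrays(self, add_self_loops: bool = False):
        """(sources, targets) arrays, optionally with (u, u) for every u."""
        src, tgt = self.edges[:, 0].copy(), self.edges[:, 1].copy()
        if add_self_loops:
            loops = np.arange(self.n_nodes, dtype=np.int64)
            src = np.concatenate([src, loops])
            tgt = np.concatenate([tgt, loops])
        return src, tgt


def knn_edges(
    features: np.ndarray, k: int, metric: str = "euclidean"
) -> KnnGraph:
    """Build the directed k-NN graph: for every node u, an edge (v -> u)
    from each of its k nearest distinct nodes v under the chosen metric.

    Distances are computed exactly (dense pairwise table); ties are broken
    toward the lower node index so construction is deterministic.
    """
    X = np.asarray(features, dtype=np.float64)
    n = X.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must satisfy 1 <= k <= n-1, got k={k}, n={n}")
    if metric == "euclidean":
        from scipy.spatial.distance import cdist

        D = cdist(X, X, metric="euclidean")
    elif metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            bad = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(f"zero-norm vector at node {bad} under cosine")
        Xn = X / norms[:, None]
        D = 1.0 - Xn @ Xn.T
    else:
        raise ValueError(f"unknown metric '{metric}'")
    np.fill_diagonal(D, np.inf)  # never pick self
    # stable argsort: among equal distances, the lower index comes first
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    tgt = np.repeat(np.arange(n, dtype=np.int64), k)
    src = nn.ravel().astype(np.int64)
    edges = np.column_stack([src, tgt])
    return KnnGraph(n_nodes=n, edges=edges, k=k, metric=metric)


def symmetrize(graph: KnnGraph) -> KnnGraph:
    """Union of the edge set with its reversal; idempotent."""
    if graph.n_edges == 0:
        edges = graph.edges
    else:
        edges = np.vstack([graph.edges, graph.edges[:, ::-1]])
    return KnnGraph(
        n_nodes=graph.n_nodes,
        edges=edges,
        k=graph.k,
        metric=graph.metric,
        symmetrized=True,
    )


def graph_matrices(graph: KnnGraph):
    """Return (A, A_tilde, D_tilde): adjacency, self-looped adjacency
    A + I, and the diagonal degree matrix of A_tilde's row sums."""
    A = graph.adjacency()
    A_tilde = (A + sp.identity(graph.n_nodes, format="csr")).tocsr()
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    D_tilde = sp.diags(deg, format="csr")
    return A, A_tilde, D_tilde


def gcn_propagation(graph: KnnGraph) -> sp.csr_matrix:
    """Symmetrically normalised propagation operator
    ``D^{-1/2} (A + I) D^{-1/2}``.

    Built over the in-neighbour orientation (column-adjacency transpose) so
    that row u aggregates over N_u plus the self-loop; for the default
    symmetrised graph this equals the textbook undirected operator.  Cached
    on the graph (structure-only, label-free).
    """
    cached = getattr(graph, "_gcn_prop", None)
    if cached is not None:
        return cached
    _, A_tilde, _ = graph_matrices(graph)
    At = A_tilde.T.tocsr()  # row u <- in-neighbours of u (+ self)
    deg = np.asarray(At.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    Dm = sp.diags(d_inv_sqrt)
    S = (Dm @ At @ Dm).tocsr()
    graph._gcn_prop = S
    return S


def mean_aggregation(graph: KnnGraph) -> sp.csr_matrix:
    """Row-stochastic mean-over-in-neighbourhood operator (no self-loops).

    Rows of isolated nodes (empty N_u) are zero, so they aggregate the zero
    vector.  Cached on the graph (structure-only, label-free).
    """
    cached = getattr(graph, "_mean_agg", None)
    if cached is not None:
        return cached
    src, tgt = graph.edge_arrays(add_self_loops=False)
    deg = np.bincount(tgt, minlength=graph.n_nodes).astype(np.float64)
    w = np.where(deg[tgt] > 0, 1.0 / deg[tgt], 0.0)
    M = sp.csr_matrix(
        (w, (tgt, src)), shape=(graph.n_nodes, graph.n_nodes)
    )
    graph._mean_agg = M
    return M


def homophily(graph: KnnGraph, labels: np.ndarray) -> float:
    """Fraction of edges joining same-label nodes; gauges how informative
    the graph is for label propagation."""
    if graph.n_edges == 0:
        return float("nan")
    labels = np.asarray(labels)
    s, t = graph.edges[:, 0], graph.edges[:, 1]
    return float((labels[s] == labels[t]).mean())
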