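"""Fast node-centrality computations on undirected, unweighted graphs.

Seven measures are provided: raw degree, betweenness, closeness,
eigenvector centrality, local clustering coefficient, load centrality and
PageRank.  They use the standard normalisations of the common graph
libraries:

* betweenness and load are scaled by ``1 / ((n-1)(n-2))`` over the directed
  pair count, equivalent to dividing the undirected pair total by
  ``(n-1)(n-2)/2``;
* closeness uses the reachable-set ("improved") formula
  ``((r-1)/(n-1)) * ((r-1)/sum_d)`` so values remain comparable on
  disconnected graphs; isolated nodes score 0;
* eigenvector centrality is the Perron vector, unit Euclidean norm,
  obtained by shifted ``(A + I)`` power iteration (the shift makes the
  iteration immune to bipartite oscillation);
* PageRank uses damping 0.85 with uniform teleport and uniform dangling
  redistribution, so scores sum to 1.

Because edgetic perturbation requires recomputing centralities for each
(mutation-specific) edge-deleted graph, the shortest-path measures are
implemented as a single Brandes-style pass over CSR adjacency arrays that
accumulates betweenness and load simultaneously; the pass is JIT-compiled
with numba when available (a pure-Python fallback with identical semantics
is used otherwise).  Results match networkx to floating-point accuracy.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)

__all__ = ["ProteinFeatures", "CsrGraph", "compute_centralities", "PROTEIN_FEATURE_NAMES"]

PROTEIN_FEATURE_NAMES = (
    "degree",
    "betweenness",
    "closeness",
    "eigenvector",
    "clustering_coefficient",
    "load",
    "pagerank",
)

PAGERANK_DAMPING = 0.85
PAGERANK_TOL = 1e-9
PAGERANK_MAX_ITER = 100
EIGENVECTOR_TOL = 1e-10
EIGENVECTOR_MAX_ITER = 1000


class ProteinFeatures(NamedTuple):
    """The seven protein-level network features of one node."""

    degree: int
    betweenness: float
    closeness: float
    eigenvector: float
    clustering_coefficient: float
    load: float
    pagerank: float


def _brandes_newman_py(indptr, indices, n):  # pragma: no cover - numba twin
    """Betweenness and load for all nodes in one pass (pure-Python twin of
    the numba kernel below; kept in sync)."""
    bet = np.zeros(n)
    load = np.zeros(n)
    dist = np.empty(n, np.int64)
    sigma = np.empty(n, np.float64)
    order = np.empty(n, np.int64)
    delta = np.empty(n, np.float64)
    amount = np.empty(n, np.float64)
    for s in range(n):
        dist[:] = -1
        sigma[:] = 0.0
        dist[s] = 0
        sigma[s] = 1.0
        order[0] = s
        head, tail = 0, 1
        while head < tail:
            v = order[head]
            head += 1
            dv = dist[v]
            for e in range(indptr[v], indptr[v + 1]):
                w = indices[e]
                if dist[w] == -1:
                    dist[w] = dv + 1
                    order[tail] = w
                    tail += 1
                if dist[w] == dv + 1:
                    sigma[w] += sigma[v]
        for i in range(tail):
            delta[order[i]] = 0.0
            amount[order[i]] = 1.0
        for i in range(tail - 1, 0, -1):
            v = order[i]
            dv = dist[v]
            npred = 0
            for e in range(indptr[v], indptr[v + 1]):
                if dist[indices[e]] == dv - 1:
                    npred += 1
            coeff = (1.0 + delta[v]) / sigma[v]
            share = amount[v] / npred
            for e in range(indptr[v], indptr[v + 1]):
                w = indices[e]
                if dist[w] == dv - 1:
                    delta[w] += sigma[w] * coeff
                    if w != s:
                        amount[w] += share
            bet[v] += delta[v]
            load[v] += amount[v] - 1.0
    if n > 2:
        scale = 1.0 / ((n - 1) * (n - 2))
        bet *= scale
        load *= scale
    return bet, load


try:  # JIT-compile the kernel when numba is importable
    from numba import njit

    _brandes_newman = njit(cache=True)(_brandes_newman_py)
except Exception:  # pragma: no cover
    logger.warning("numba unavailable; using pure-Python shortest-path kernel")
    _brandes_newman = _brandes_newman_py


class CsrGraph:
    """Immutable CSR view of an undirected graph with centrality methods.

    Node identity is positional; :func:`compute_centralities` handles the
    mapping from labelled graphs.  Betweenness/load results are cached since
    they are the dominant cost and are shared by all per-node queries.
    """

    def __init__(self, adjacency: sp.csr_matrix):
        adjacency = adjacency.tocsr()
        self.adj = adjacency
        self.n = adjacency.shape[0]
        self.indptr = adjacency.indptr.astype(np.int64)
        self.indices = adjacency.indices.astype(np.int64)
        self.degrees = np.diff(self.indptr)
        self._bet_load: tuple[np.ndarray, np.ndarray] | None = None
        self._eigenvector: np.ndarray | None = None
        self._pagerank: np.ndarray | None = None

    @classmethod
    def from_graph(cls, graph: nx.Graph, nodelist: list) -> "CsrGraph":
        n = len(nodelist)
        if n == 0:
            return cls(sp.csr_matrix((0, 0)))
        adj = nx.to_scipy_sparse_array(
            graph, nodelist=nodelist, dtype=np.float64, format="csr"
        )
        return cls(sp.csr_matrix(adj))

    def without_edges(self, edge_indices: list[tuple[int, int]]) -> "CsrGraph":
        """A copy with the given (i, j) edges removed; nodes are retained."""
        if not edge_indices:
            return self
        adj = self.adj.tolil(copy=True)
        for i, j in edge_indices:
            adj[i, j] = 0
            adj[j, i] = 0
        out = adj.tocsr()
        out.eliminate_zeros()
        return CsrGraph(out)

    # -- measures -------------------------------------------------------

    def degree(self, i: int) -> int:
        return int(self.degrees[i])

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def betweenness_load(self) -> tuple[np.ndarray, np.ndarray]:
        if self._bet_load is None:
            if self.n == 0:
                z = np.zeros(0)
                self._bet_load = (z, z.copy())
            else:
                self._bet_load = _brandes_newman(self.indptr, self.indices, self.n)
        return self._bet_load

    def closeness(self, i: int) -> float:
        """Reachable-set scaled closeness of node i."""
        if self.n <= 1 or self.degrees[i] == 0:
            return 0.0
        dist = shortest_path(
            self.adj, method="D", unweighted=True, indices=i, directed=False
        )
        reached = np.isfinite(dist)
        r = int(reached.sum())  # includes i itself
        if r <= 1:
            return 0.0
        total = dist[reached].sum()
        return ((r - 1) / (self.n - 1)) * ((r - 1) / total)

    def clustering(self, i: int) -> float:
        """Local clustering coefficient: triangle density among neighbours."""
        nbrs = self.neighbors(i)
        d = len(nbrs)
        if d < 2:
            return 0.0
        nbr_set = set(nbrs.tolist())
        links = 0
        for u in nbrs:
            for w in self.neighbors(int(u)):
                if int(w) in nbr_set:
                    links += 1
        return links / (d * (d - 1))  # each triangle edge counted twice

    def eigenvector(self) -> np.ndarray:
        """Principal eigenvector (unit L2 norm) by shifted power iteration."""
        if self._eigenvector is not None:
            return self._eigenvector
        n = self.n
        if n == 0:
            return np.zeros(0)
        if self.adj.nnz == 0:
            self._eigenvector = np.zeros(n)
            return self._eigenvector
        x = np.full(n, 1.0 / n)
        for _ in range(EIGENVECTOR_MAX_ITER):
            xlast = x
            x = xlast + self.adj @ xlast
            norm = np.linalg.norm(x) or 1.0
            x = x / norm
            if np.abs(x - xlast).sum() < n * EIGENVECTOR_TOL:
                break
        else:
            logger.warning(
                "eigenvector power iteration did not converge in %d steps",
                EIGENVECTOR_MAX_ITER,
            )
        self._eigenvector = x
        return x

    def pagerank(self) -> np.ndarray:
        """PageRank with damping 0.85; scores sum to 1."""
        if self._pagerank is not None:
            return self._pagerank
        n = self.n
        if n == 0:
            return np.zeros(0)
        alpha = PAGERANK_DAMPING
        deg = self.degrees.astype(np.float64)
        dangling = deg == 0
        inv_deg = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
        x = np.full(n, 1.0 / n)
        for _ in range(PAGERANK_MAX_ITER):
            xlast = x
            spread = self.adj @ (xlast * inv_deg)
            dangling_mass = xlast[dangling].sum()
            x = alpha * (spread + dangling_mass / n) + (1.0 - alpha) / n
            if np.abs(x - xlast).sum() < n * PAGERANK_TOL:
                break
        else:
            logger.warning(
                "pagerank did not converge in %d steps", PAGERANK_MAX_ITER
            )
        self._pagerank = x
        return x

    def node_features(self, i: int) -> ProteinFeatures:
        bet, load = self.betweenness_load()
        return ProteinFeatures(
            degree=self.degree(i),
            betweenness=float(bet[i]),
            closeness=self.closeness(i),
            eigenvector=float(self.eigenvector()[i]),
            clustering_coefficient=self.clustering(i),
            load=float(load[i]),
            pagerank=float(self.pagerank()[i]),
        )


def compute_centralities(graph: nx.Graph, nodelist: list | None = None):
    """All seven centrality measures for every node of ``graph``.

    Returns a ``pandas.DataFrame`` indexed by node with one column per
    measure (see :data:`PROTEIN_FEATURE_NAMES`).  Nodes are processed in
    sorted order, so results are deterministic.
    """
    import pandas as pd

    if nodelist is None:
        nodelist = sorted(graph.nodes)
    csr = CsrGraph.from_graph(graph, nodelist)
    bet, load = csr.betweenness_load()
    eig = csr.eigenvector()
    pr = csr.pagerank()
    rows = []
    for i in range(csr.n):
        rows.append(
            (
                csr.degree(i),
                bet[i],
                csr.closeness(i),
                eig[i],
                csr.clustering(i),
                load[i],
                pr[i],
            )
        )
    return pd.DataFrame(rows, index=nodelist, columns=list(PROTEIN_FEATURE_NAMES))
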