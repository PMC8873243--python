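"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive: explicit BFS with path enumeration
for the shortest-path measures, dense linear algebra for the spectral ones,
and O(n_pos * n_neg) pair loops for ranking metrics.  None of it shares
code with the package.
"""

from collections import deque
from itertools import combinations

import numpy as np


def bfs_dist_preds(adj: dict, s):
    """BFS from s: distances and shortest-path predecessor lists."""
    dist = {s: 0}
    preds: dict = {s: []}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                preds[w] = [v]
                queue.append(w)
            elif dist[w] == dist[v] + 1:
                preds[w].append(v)
    return dist, preds


def enumerate_shortest_paths(preds: dict, s, t):
    """All shortest s->t paths by backtracking the predecessor DAG."""
    if t not in preds:
        return []
    out = []

    def walk(node, suffix):
        if node == s:
            out.append([s] + suffix)
            return
        for p in preds[node]:
            walk(p, [node] + suffix)

    walk(t, [])
    return out


def _adj(graph) -> dict:
    return {v: sorted(graph.neighbors(v)) for v in graph.nodes}


def brute_betweenness(graph) -> dict:
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    adj = _adj(graph)
    nodes = sorted(adj)
    n = len(nodes)
    bet = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist, preds = bfs_dist_preds(adj, s)
        paths = enumerate_shortest_paths(preds, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bet[v] += 1.0 / len(paths)
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bet = {v: b * scale for v, b in bet.items()}
    return bet


def brute_load(graph) -> dict:
    """Normalized load: unit packets routed to each target, split equally
    among shortest-path predecessors at every branch point."""
    adj = _adj(graph)
    nodes = sorted(adj)
    n = len(nodes)
    load = {v: 0.0 for v in nodes}
    for s in nodes:
        dist, preds = bfs_dist_preds(adj, s)
        packets = {v: 1.0 for v in dist}
        for v in sorted(dist, key=lambda u: -dist[u]):
            if v == s:
                continue
            share = packets[v] / len(preds[v])
            for u in preds[v]:
                if u != s:
                    packets[u] += share
        for v in dist:
            if v != s:
                load[v] += packets[v] - 1.0
    if n > 2:
        load = {v: x / ((n - 1) * (n - 2)) for v, x in load.items()}
    return load


def brute_closeness(graph, v) -> float:
    """Reachable-set scaled closeness from explicit BFS distances."""
    adj = _adj(graph)
    n = len(adj)
    dist, _ = bfs_dist_preds(adj, v)
    r = len(dist)
    if n <= 1 or r <= 1:
        return 0.0
    total = sum(dist.values())
    return ((r - 1) / (n - 1)) * ((r - 1) / total)


def brute_clustering(graph, v) -> float:
    nbrs = set(graph.neighbors(v))
    d = len(nbrs)
    if d < 2:
        return 0.0
    links = sum(1 for a, b in combinations(sorted(nbrs), 2) if graph.has_edge(a, b))
    return 2.0 * links / (d * (d - 1))


def brute_eigenvector(graph) -> dict:
    """Dense shifted power iteration run to near machine precision."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for a, b in graph.edges:
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1.0
    if A.sum() == 0:
        return {v: 0.0 for v in nodes}
    x = np.full(n, 1.0 / n)
    for _ in range(200000):
        xn = x + A @ x
        xn /= np.linalg.norm(xn)
        if np.abs(xn - x).sum() < n * 1e-15:
            x = xn
            break
        x = xn
    return {v: float(x[idx[v]]) for v in nodes}


def brute_pagerank(graph, alpha=0.85) -> dict:
    """PageRank by dense linear solve (no iteration)."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))  # column-stochastic transition
    for v in nodes:
        nbrs = sorted(graph.neighbors(v))
        j = idx[v]
        if nbrs:
            for w in nbrs:
                M[idx[w], j] = 1.0 / len(nbrs)
        else:
            M[:, j] = 1.0 / n  # dangling: uniform
    x = np.linalg.solve(np.eye(n) - alpha * M, np.full(n, (1 - alpha) / n))
    x = x / x.sum()
    return {v: float(x[idx[v]]) for v in nodes}


def brute_auroc(scores, labels) -> float:
    """Exhaustive pair counting; ties score half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
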