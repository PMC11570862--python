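"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid networkx and the package's own implementations:
shortest paths come from Floyd–Warshall on an adjacency matrix and path
counts from explicit enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np

INF = float("inf")


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = len(adj)
    dist = np.where(adj > 0, 1.0, INF)
    np.fill_diagonal(dist, 0.0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    return dist


def eccentricity_oracle(adj: np.ndarray, v: int) -> int:
    """Max hop distance from v to any reachable node (BFS-free: FW matrix)."""
    dist = floyd_warshall(adj)
    reachable = dist[v][dist[v] < INF]
    return int(reachable.max())


def _count_shortest_paths(adj: np.ndarray, dist: np.ndarray, s: int, t: int):
    """All shortest s→t paths by depth-first enumeration over the FW matrix."""
    if dist[s, t] == INF:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for w in range(len(adj)):
            if adj[u, w] and dist[u, t] == dist[w, t] + 1:
                extend(path + [w])

    extend([s])
    return paths

def betweenness_oracle(adj: np.ndarray, v: int) -> float:
    """Normalized betweenness of v by exhaustive shortest-path enumeration."""
    n = len(adj)
    if n < 3:
        return 0.0
    dist = floyd_warshall(adj)
    total = 0.0
    for s, t in itertools.combinations(range(n), 2):
        if v in (s, t):
            continue
        paths = _count_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        through = sum(1 for p in paths if v in p[1:-1])
        total += through / len(paths)
    return total / ((n - 1) * (n - 2) / 2)


def random_graph(n: int, p: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            adj[i, j] = adj[j, i] = 1
    return adj
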