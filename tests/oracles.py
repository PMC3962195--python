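"""Independent brute-force oracles used across the test suite.

Everything here works by exhaustive enumeration on small inputs and shares
no code with the implementation it checks.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def enumerate_shortest_paths(adj: dict, s, t) -> list[list]:
    """All geodesics s->t by DFS over simple paths of the geodesic length."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    target_len = dist[t]
    out: list[list] = []

    def dfs(path: list):
        u = path[-1]
        if len(path) - 1 == target_len:
            if u == t:
                out.append(list(path))
            return
        for v in adj[u]:
            if v not in path:
                dfs(path + [v])

    dfs([s])
    return out


def brute_force_centralities(adj: dict) -> dict:
    """degree/closeness/betweenness by explicit geodesic enumeration.

    closeness(v) = (n_c - 1) / sum of distances within v's component;
    betweenness(v) = sum over pairs (s, t) != v in v's component of
    (#geodesics through v) / (#geodesics), normalized by
    (n_c - 1)(n_c - 2) / 2.
    """
    nodes = sorted(adj)
    deg = {v: len(adj[v]) for v in nodes}
    closeness = {}
    betweenness = {v: 0.0 for v in nodes}
    comp_of = {}
    comp_sizes = {}
    for v in nodes:
        if v in comp_of:
            continue
        comp = sorted(bfs_distances(adj, v))
        for u in comp:
            comp_of[u] = v
            comp_sizes[u] = len(comp)
    for v in nodes:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        closeness[v] = (len(dist) - 1) / total if total > 0 else 0.0
    for s, t in combinations(nodes, 2):
        if comp_of[s] != comp_of[t]:
            continue
        paths = enumerate_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            betweenness[v] += through / len(paths)
    for v in nodes:
        n_c = comp_sizes[v]
        norm = (n_c - 1) * (n_c - 2) / 2
        betweenness[v] = betweenness[v] / norm if norm > 0 else 0.0
    return {"degree": deg, "closeness": closeness, "betweenness": betweenness}


def sp_network_oracle(adj: dict, seeds, max_len: int):
    """Union of all seed-seed geodesics of length <= max_len.

    Returns (node set, set of unordered edge pairs).
    """
    seeds = [s for s in seeds if s in adj]
    nodes, edges = set(), set()
    for s, t in combinations(sorted(seeds), 2):
        dist = bfs_distances(adj, s)
        if t not in dist or dist[t] > max_len:
            continue
        for path in enumerate_shortest_paths(adj, s, t):
            nodes.update(path)
            for a, b in zip(path, path[1:]):
                edges.add((min(a, b), max(a, b)))
    return nodes, edges


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by direct combinatorial summation."""
    denom = math.comb(N, n)
    total = 0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i)
    return total / denom


def bh_stepup(pvals: list[float]) -> list[float]:
    """Hand application of the Benjamini-Hochberg step-up rule."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def pooled_t(x1, x2) -> float:
    """Ordinary pooled-variance two-sample t."""
    n1, n2 = len(x1), len(x2)
    m1 = sum(x1) / n1
    m2 = sum(x2) / n2
    ss = sum((v - m1) ** 2 for v in x1) + sum((v - m2) ** 2 for v in x2)
    s2 = ss / (n1 + n2 - 2)
    return (m1 - m2) / math.sqrt(s2 * (1 / n1 + 1 / n2))
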