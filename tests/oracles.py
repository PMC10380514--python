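"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (BFS, subset enumeration,
exhaustive combinatorics) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb, factorial


# --------------------------------------------------------------------------
# graph centralities (adjacency given as dict node -> set of neighbors)


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


def harmonic_closeness(adj: dict, v) -> float:
    dist = bfs_distances(adj, v)
    return sum(1.0 / d for u, d in dist.items() if u != v)


def _all_shortest_paths(adj: dict, s, t) -> list[tuple]:
    """All shortest s-t paths by DFS over the BFS distance layers."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for w in adj[u]:
            if dist.get(w) == dist[u] + 1 and dist[w] <= dist[t]:
                extend(path + [w])

    extend([s])
    return paths


def betweenness_ordered(adj: dict, v) -> float:
    """Ordered-pair shortest-path betweenness by explicit path enumeration."""
    total = 0.0
    nodes = [u for u in adj if u != v]
    for s, t in itertools.permutations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t)
        if not paths:
            continue
        through = sum(1 for p in paths if v in p[1:-1])
        total += through / len(paths)
    return total


def is_clique(adj: dict, subset) -> bool:
    return all(b in adj[a] for a, b in itertools.combinations(subset, 2))


def maximal_cliques(adj: dict) -> list[frozenset]:
    """Naive maximal-clique enumeration by testing every node subset."""
    nodes = sorted(adj)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if not is_clique(adj, subset):
                continue
            s = set(subset)
            if any(is_clique(adj, s | {w}) for w in nodes if w not in s):
                continue
            cliques.append(frozenset(s))
    return cliques


def mcc(adj: dict, v) -> int:
    return sum(factorial(len(c) - 1) for c in maximal_cliques(adj) if v in c)


# --------------------------------------------------------------------------
# statistics


def hypergeom_upper_exact(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by exact summation over the hypergeometric pmf."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


def hypergeom_upper_enumerated(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every size-n draw from the universe."""
    marked = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def bh_step_up(p_values):
    """Benjamini-Hochberg adjusted p-values straight from the step-up
    definition: q_(i) = min_{j >= i} min(1, m p_(j) / j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p_values[i] / rank)
        adjusted[i] = min(1.0, running)
    return adjusted


def ks_statistic_signed(in_set, n_total) -> float:
    """Signed two-sample KS statistic between the hit and miss step
    functions over ranked positions (``in_set``: boolean per rank)."""
    n_hit = sum(in_set)
    n_miss = n_total - n_hit
    best = 0.0
    f_hit = f_miss = 0.0
    for flag in in_set:
        if flag:
            f_hit += 1.0 / n_hit
        else:
            f_miss += 1.0 / n_miss
        d = f_hit - f_miss
        if abs(d) > abs(best):
            best = d
    return best
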