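"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (exhaustive path
enumeration, combinatorial tail sums, literal draw enumeration) and
deliberately avoids the library routines it is used to verify.
"""

from __future__ import annotations

import itertools
from math import comb
from typing import Mapping, Sequence


Adjacency = Mapping[str, Sequence[str]]


def _all_simple_paths(adj: Adjacency, s: str, t: str) -> list[list[str]]:
    out: list[list[str]] = []

    def dfs(node: str, path: list[str], visited: set[str]) -> None:
        if node == t:
            out.append(path[:])
            return
        for nb in sorted(adj[node]):
            if nb not in visited:
                visited.add(nb)
                path.append(nb)
                dfs(nb, path, visited)
                path.pop()
                visited.remove(nb)

    dfs(s, [s], {s})
    return out


def _shortest_paths(adj: Adjacency, s: str, t: str) -> list[list[str]]:
    paths = _all_simple_paths(adj, s, t)
    if not paths:
        return []
    shortest = min(len(p) for p in paths)
    return [p for p in paths if len(p) == shortest]


def brute_betweenness(adj: Adjacency) -> dict[str, float]:
    """Pair-normalized betweenness by enumerating every simple path."""
    nodes = sorted(adj)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    if n < 3:
        return bc
    for s, t in itertools.combinations(nodes, 2):
        shortest = _shortest_paths(adj, s, t)
        if not shortest:
            continue
        sigma = len(shortest)
        for path in shortest:
            for v in path[1:-1]:
                bc[v] += 1.0 / sigma
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: x * scale for v, x in bc.items()}


def brute_closeness(adj: Adjacency) -> dict[str, float]:
    """Component-scaled (Wasserman–Faust) closeness from enumerated paths."""
    nodes = sorted(adj)
    n = len(nodes)
    out: dict[str, float] = {}
    for v in nodes:
        dists = {}
        for u in nodes:
            if u == v:
                continue
            shortest = _shortest_paths(adj, v, u)
            if shortest:
                dists[u] = len(shortest[0]) - 1
        n_v = len(dists) + 1
        if n_v == 1 or n == 1:
            out[v] = 0.0
        else:
            out[v] = ((n_v - 1) / (n - 1)) * ((n_v - 1) / sum(dists.values()))
    return out


def hypergeom_tail_comb(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) as an exact ratio of binomial-coefficient sums."""
    denom = comb(N, n)
    hi = min(n, K)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, hi + 1)) / denom


def hypergeom_tail_draws(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by literally enumerating every C(N, n) draw."""
    annotated = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total
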