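"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_shortest_paths(W: np.ndarray, s: int, t: int, rtol: float = 1e-12):
    """All simple shortest s->t paths by summed 1/w edge lengths.

    Exhaustive DFS over simple paths; lengths within a relative tolerance
    of the minimum count as tied. Returns (best_length, paths);
    (inf, []) when t is unreachable from s.
    """
    n = W.shape[0]
    all_paths: list[tuple[list[int], float]] = []

    def dfs(path, length):
        u = path[-1]
        if u == t:
            all_paths.append((list(path), length))
            return
        for v in range(n):
            if W[u, v] > 0 and v not in path:
                dfs(path + [v], length + 1.0 / W[u, v])

    if s == t:
        return np.inf, []
    dfs([s], 0.0)
    if not all_paths:
        return np.inf, []
    best = min(l for _, l in all_paths)
    tol = rtol * max(1.0, abs(best))
    return best, [p for p, l in all_paths if l <= best + tol]


def brute_betweenness(W: np.ndarray) -> np.ndarray:
    """Fractional betweenness by exhaustive path enumeration (endpoints excluded)."""
    n = W.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        _best, paths = enumerate_shortest_paths(W, s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def brute_clustering(W: np.ndarray, i: int):
    """Clustering coefficient by direct recount of partner pairs."""
    n = W.shape[0]
    partners = [j for j in range(n) if j != i and (W[i, j] > 0 or W[j, i] > 0)]
    k = len(partners)
    if k < 2:
        return None
    linked = 0
    for a in range(k):
        for b in range(a + 1, k):
            u, v = partners[a], partners[b]
            if W[u, v] > 0 or W[v, u] > 0:
                linked += 1
    return linked / (k * (k - 1) / 2)


def random_weighted_digraph(rng: np.random.Generator, n: int, p: float = 0.5):
    """Random directed weighted graph with continuous weights (no exact ties)."""
    W = np.where(rng.random((n, n)) < p, rng.uniform(0.5, 2.0, (n, n)), 0.0)
    np.fill_diagonal(W, 0.0)
    return W


def one_way_data(
    rng: np.random.Generator, n_groups: int, reps: int, repeatability: float,
    total_var: float = 1.0,
):
    """Balanced one-way random-effects data with known repeatability."""
    s2a = repeatability * total_var
    s2e = total_var - s2a
    a = rng.normal(0, np.sqrt(s2a), n_groups)
    y = np.repeat(a, reps) + rng.normal(0, np.sqrt(s2e), n_groups * reps)
    groups = np.repeat([f"g{k}" for k in range(n_groups)], reps)
    return y, groups
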