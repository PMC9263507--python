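"""Independent brute-force oracles for path-based graph quantities.

These enumerate simple paths exhaustively and never touch the package's
shortest-path or betweenness code, so they can certify it on small graphs.
"""

from __future__ import annotations

import itertools

import numpy as np


def all_simple_paths(adj: np.ndarray, s: int, t: int) -> list[list[int]]:
    """All simple s->t paths in the graph of nonzero entries of adj."""
    n = adj.shape[0]
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for nxt in range(n):
            if adj[last, nxt] > 0 and nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([s])
    return paths


def path_length(weights: np.ndarray, path: list[int]) -> float:
    return sum(1.0 / weights[a, b] for a, b in zip(path, path[1:]))


def brute_distances(weights: np.ndarray) -> np.ndarray:
    """Minimal 1/weight path length over all simple paths; inf if none."""
    n = weights.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_simple_paths(weights, s, t)
        if paths:
            D[s, t] = D[t, s] = min(path_length(weights, p) for p in paths)
    return D


def brute_betweenness(weights: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Fraction of shortest paths through each node, summed over unordered
    source-target pairs (endpoints excluded)."""
    n = weights.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_simple_paths(weights, s, t)
        if not paths:
            continue
        lengths = [path_length(weights, p) for p in paths]
        dmin = min(lengths)
        shortest = [p for p, l in zip(paths, lengths) if l <= dmin + tol]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def random_weighted_graph(rng: np.random.Generator, n: int, p_edge: float = 0.6) -> np.ndarray:
    """Random symmetric weighted adjacency with weights in [0.1, 1]."""
    w = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p_edge:
            w[i, j] = w[j, i] = rng.uniform(0.1, 1.0)
    return w
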