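"""Global and nodal graph-theory metrics on weighted connectomes.

Edge weights (FA) are affinities; path computations use the standard
length transform ``length = 1/weight`` (a ``neg_log`` alternative is
available for weights in (0, 1)). Disconnected pairs contribute 0 to
efficiencies and are excluded from path-length means.

Small-worldness is assessed against degree-preserving Maslov-Sneppen
rewired null networks in which each rewired edge carries its weight to its
new endpoints: gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null>,
sigma = gamma/lambda.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

try:  # compiled swap loop; the pure-Python fallback is semantically identical
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

from .core import ConnectivityMatrix

__all__ = [
    "NullModelConfig",
    "NodalMetrics",
    "GlobalMetrics",
    "shortest_distances",
    "nodal_metrics",
    "global_metrics",
    "rewire_preserving_degree",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullModelConfig:
    """Settings for the degree-preserving random null ensemble."""

    n_null: int = 100
    rewires_per_edge: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.rewires_per_edge < 1:
            raise ValueError("rewires_per_edge must be >= 1")


def _length_matrix(w: np.ndarray, transform: str) -> np.ndarray:
    """Edge lengths from weights; absent edges get +inf."""
    L = np.full_like(w, np.inf)
    mask = w > 0
    if transform == "inverse":
        L[mask] = 1.0 / w[mask]
    elif transform == "neg_log":
        if (w[mask] >= 1).any():
            raise ValueError("neg_log transform requires weights < 1")
        L[mask] = -np.log(w[mask])
    else:
        raise ValueError(f"unknown length transform {transform!r}")
    return L


def shortest_distances(
    matrix: ConnectivityMatrix, transform: str = "inverse"
) -> np.ndarray:
    """All-pairs weighted shortest-path distances.

    Distance is the minimal sum of edge lengths with length(i,j) =
    1/weight(i,j) by default; unreachable pairs are +inf, the diagonal 0.
    """
    w = matrix.weights
    L = _length_matrix(w, transform)
    finite = np.isfinite(L)
    graph = csr_matrix((L[finite], np.nonzero(finite)), shape=w.shape)
    D = _sp_shortest_path(graph, method="D", directed=False)
    return D


def _clustering(w: np.ndarray, mode: str) -> np.ndarray:
    """Per-node clustering coefficient.

    Binary: triangle density among neighbors. Weighted: Onnela geometric-mean
    form with weights normalized by the network maximum.
    """
    n = w.shape[0]
    if n < 3:
        raise ValueError("clustering coefficient requires at least 3 nodes")
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    if mode == "binary":
        cyc = np.diagonal(a @ a @ a)
    elif mode == "weighted":
        wmax = w.max()
        if wmax == 0:
            return np.zeros(n)
        wh = np.cbrt(w / wmax)
        cyc = np.diagonal(wh @ wh @ wh)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, cyc / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def _betweenness(matrix: ConnectivityMatrix, mode: str, transform: str) -> np.ndarray:
    """Brandes betweenness: shortest paths through each node, counted over
    unordered source-target pairs, split fractionally over ties."""
    g = nx.Graph()
    n = matrix.n_nodes
    g.add_nodes_from(range(n))
    for i, j, wt in matrix.edge_list():
        if mode == "weighted":
            length = 1.0 / wt if transform == "inverse" else -np.log(wt)
            g.add_edge(i, j, length=length)
        else:
            g.add_edge(i, j)
    weight = "length" if mode == "weighted" else None
    bc = nx.betweenness_centrality(g, normalized=False, weight=weight)
    return np.array([bc[i] for i in range(n)])


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node metric arrays (length N, aligned with node indices)."""

    dc: np.ndarray  # binary degree centrality
    strength: np.ndarray  # sum of edge weights
    bc: np.ndarray  # betweenness centrality (unnormalized pair counts)
    nlp: np.ndarray  # nodal shortest path length (mean finite distance)
    ncc: np.ndarray  # nodal clustering coefficient
    ne: np.ndarray  # nodal efficiency (mean inverse distance)
    mode: str = "weighted"

    #: Metric names in reporting order.
    NAMES = ("dc", "strength", "bc", "nlp", "ncc", "ne")

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.NAMES}


def nodal_metrics(
    matrix: ConnectivityMatrix, mode: str = "weighted", transform: str = "inverse"
) -> NodalMetrics:
    """Compute all regional metrics for one subject.

    dc is always the binary degree (with strength alongside); bc, nlp and ne
    use 1/weight path lengths in weighted mode and hop counts in binary mode;
    ncc uses the Onnela weighted form or binary triangle density.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"mode must be binary or weighted, got {mode!r}")
    w = matrix.weights if mode == "weighted" else matrix.binary()
    m = ConnectivityMatrix(weights=w, subject_id=matrix.subject_id)
    D = shortest_distances(m, transform=transform if mode == "weighted" else "inverse")
    n = matrix.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    with np.errstate(invalid="ignore"):
        nlp = np.where(
            finite.sum(axis=1) > 0,
            np.where(finite, D, 0.0).sum(axis=1) / np.maximum(finite.sum(axis=1), 1),
            np.inf,
        )
    inv = np.zeros_like(D)
    inv[finite] = 1.0 / D[finite]
    ne = inv.sum(axis=1) / (n - 1)
    return NodalMetrics(
        dc=matrix.degrees(),
        strength=matrix.strengths(),
        bc=_betweenness(matrix, mode, transform),
        nlp=nlp,
        ncc=_clustering(w, mode),
        ne=ne,
        mode=mode,
    )


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network summary metrics for one subject."""

    cp: float  # global clustering coefficient (mean nodal clustering)
    lp: float  # characteristic path length (mean over finite pairs)
    eglob: float  # global efficiency (mean inverse distance, inf -> 0)
    strength: float  # mean node strength
    gamma: float = np.nan  # cp / <cp_null>
    lam: float = np.nan  # lp / <lp_null>
    sigma: float = np.nan  # gamma / lam; > 1 flags small-world organization

    def as_dict(self) -> dict[str, float]:
        return {
            "cp": self.cp,
            "lp": self.lp,
            "eglob": self.eglob,
            "strength": self.strength,
            "gamma": self.gamma,
            "lam": self.lam,
            "sigma": self.sigma,
        }


def _cp_lp(matrix: ConnectivityMatrix, mode: str, transform: str) -> tuple[float, float]:
    w = matrix.weights if mode == "weighted" else matrix.binary()
    D = shortest_distances(
        ConnectivityMatrix(weights=w), transform=transform if mode == "weighted" else "inverse"
    )
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    lp = float(D[finite].mean()) if finite.any() else np.inf
    cp = float(_clustering(w, mode).mean())
    return cp, lp


def global_metrics(
    matrix: ConnectivityMatrix,
    nulls: NullModelConfig | None = None,
    mode: str = "weighted",
    transform: str = "inverse",
) -> GlobalMetrics:
    """Global network metrics, optionally with small-world normalization.

    When ``nulls`` is given, gamma/lambda/sigma are computed against
    ``nulls.n_null`` degree-preserving rewired networks (reproducible given
    ``nulls.seed``). Raises ``ValueError`` on edgeless matrices.
    """
    if matrix.n_edges == 0:
        raise ValueError("global metrics undefined for an edgeless matrix")
    w = matrix.weights if mode == "weighted" else matrix.binary()
    cp, lp = _cp_lp(matrix, mode, transform)
    D = shortest_distances(
        ConnectivityMatrix(weights=w), transform=transform if mode == "weighted" else "inverse"
    )
    n = matrix.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    inv = np.zeros_like(D)
    inv[finite] = 1.0 / D[finite]
    eglob = float(inv[off].mean())
    strength = float(matrix.strengths().mean())
    gamma = lam = sigma = np.nan
    if nulls is not None:
        seeds = np.random.SeedSequence(nulls.seed).spawn(nulls.n_null)
        cps, lps = [], []
        for ss in seeds:
            null = rewire_preserving_degree(matrix, nulls, rng=np.random.default_rng(ss))
            c0, l0 = _cp_lp(null, mode, transform)
            cps.append(c0)
            lps.append(l0)
        cp_null = float(np.mean(cps))
        lp_null = float(np.mean(lps))
        gamma = cp / cp_null if cp_null > 0 else np.nan
        lam = lp / lp_null if np.isfinite(lp_null) and lp_null > 0 else np.nan
        sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam > 0 else np.nan
    return GlobalMetrics(cp=cp, lp=lp, eglob=eglob, strength=strength, gamma=gamma, lam=lam, sigma=sigma)


def rewire_preserving_degree(
    matrix: ConnectivityMatrix,
    config: NullModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> ConnectivityMatrix:
    """Maslov-Sneppen double-edge swaps preserving every node's binary degree.

    Each accepted swap replaces edges (a,b),(c,d) with (a,d),(c,b); the
    weight of each original edge travels with its swapped replacement, so the
    weight multiset is preserved alongside the degree sequence. The target is
    ``rewires_per_edge * n_edges`` successful swaps within a bounded attempt
    budget; graphs admitting no valid swap (e.g. a triangle) are returned
    unchanged after the budget, with the realized swap count logged.
    """
    if config is None:
        config = NullModelConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    edges = matrix.edge_list()
    m = len(edges)
    if m < 2:
        return matrix
    u = np.array([e[0] for e in edges], dtype=np.int64)
    v = np.array([e[1] for e in edges], dtype=np.int64)
    wts = np.array([e[2] for e in edges])
    A = matrix.weights > 0
    target = config.rewires_per_edge * m
    max_tries = 20 * target
    picks = rng.integers(0, m, size=(max_tries, 2))
    flips = rng.random(max_tries) < 0.5
    swaps = _swap_loop(u, v, A, picks[:, 0], picks[:, 1], flips, target)
    if swaps < target:
        logger.debug("rewiring achieved %d/%d swaps", swaps, target)
    w_new = np.zeros_like(matrix.weights)
    w_new[u, v] = wts
    w_new[v, u] = wts
    return ConnectivityMatrix.from_array(w_new, subject_id=matrix.subject_id)


def _swap_loop_py(u, v, A, picks1, picks2, flips, target):
    """Sequential double-edge swaps; mutates u, v, A in place."""
    swaps = 0
    for t in range(picks1.shape[0]):
        if swaps >= target:
            break
        e1 = picks1[t]
        e2 = picks2[t]
        if e1 == e2:
            continue
        a, b = u[e1], v[e1]
        if flips[t]:
            c, d = v[e2], u[e2]
        else:
            c, d = u[e2], v[e2]
        if a == c or a == d or b == c or b == d:
            continue
        if A[a, d] or A[c, b]:
            continue
        A[a, b] = A[b, a] = False
        A[c, d] = A[d, c] = False
        A[a, d] = A[d, a] = True
        A[c, b] = A[b, c] = True
        u[e1], v[e1] = (a, d) if a < d else (d, a)
        u[e2], v[e2] = (c, b) if c < b else (b, c)
        swaps += 1
    return swaps


_swap_loop = _njit(cache=False)(_swap_loop_py) if _njit is not None else _swap_loop_py
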