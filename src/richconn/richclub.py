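"""Rich-club coefficients, hub identification and edge classification.

A network's rich club at level k is the subgraph over nodes with binary
degree > k. Two coefficients are reported side by side: phi(k), the density
of connections within the club (edges present over edges possible), and
phi_w(k), the mean weight of the club's present edges. phi(k) is undefined
(flagged, never silently zero) when the club has fewer than 2 nodes.

Hubs are found on the degree profile averaged across all subjects of the
supplied groups, either as the top-k highest-degree nodes (the study rule,
k=13) or as nodes at least one standard deviation above the network mean.
Edges are then classed rich-club (both endpoints hubs), feeder (exactly
one) or local (neither).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, SubjectRecord
from .metrics import NullModelConfig, rewire_preserving_degree

__all__ = [
    "RichClubCurve",
    "HubSet",
    "rich_club_coefficient",
    "rich_club_curve",
    "normalized_rich_club",
    "identify_hubs",
    "hubs_from_profile",
    "classify_edges",
    "count_abnormal_per_node",
]


def rich_club_coefficient(matrix: ConnectivityMatrix, k: int) -> tuple[float, float]:
    """(phi, phi_w) at degree level k.

    phi = 2 E_club / (n_club (n_club - 1)); phi_w = mean weight over the
    club's present edges. Returns (nan, nan) when the club has < 2 nodes;
    phi_w is nan when the club has no internal edges.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    deg = matrix.degrees()
    club = deg > k
    n_club = int(club.sum())
    if n_club < 2:
        return (np.nan, np.nan)
    sub = matrix.weights[np.ix_(club, club)]
    iu = np.triu_indices(n_club, k=1)
    wvals = sub[iu]
    present = wvals > 0
    e_club = int(present.sum())
    phi = 2.0 * e_club / (n_club * (n_club - 1))
    phi_w = float(wvals[present].mean()) if e_club > 0 else np.nan
    return (phi, phi_w)


@dataclass(frozen=True)
class RichClubCurve:
    """phi(k) over a range of k, with optional null normalization.

    ``defined[i]`` is False where the club at ``k_values[i]`` has fewer than
    2 nodes (phi entries there are nan, never zero)."""

    k_values: np.ndarray
    phi: np.ndarray
    phi_w: np.ndarray
    defined: np.ndarray
    phi_norm: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {
            "k": self.k_values,
            "phi": self.phi,
            "phi_w": self.phi_w,
            "defined": self.defined,
        }
        if self.phi_norm is not None:
            d["phi_norm"] = self.phi_norm
        return pd.DataFrame(d)


def rich_club_curve(
    matrix: ConnectivityMatrix, k_values: Sequence[int] | None = None
) -> RichClubCurve:
    """phi/phi_w across k (default 0 .. max degree - 1)."""
    if k_values is None:
        kmax = int(matrix.degrees().max())
        k_values = np.arange(max(kmax, 1))
    k_values = np.asarray(list(k_values), dtype=int)
    phi = np.empty(len(k_values))
    phi_w = np.empty(len(k_values))
    for idx, k in enumerate(k_values):
        phi[idx], phi_w[idx] = rich_club_coefficient(matrix, int(k))
    defined = ~np.isnan(phi)
    return RichClubCurve(k_values=k_values, phi=phi, phi_w=phi_w, defined=defined)


def normalized_rich_club(
    matrix: ConnectivityMatrix,
    nulls: NullModelConfig,
    k_values: Sequence[int] | None = None,
) -> RichClubCurve:
    """phi(k) normalized by its mean over degree-preserving rewired nulls.

    phi_norm(k) = phi(k) / <phi_null(k)>; nan where the observed curve or
    every null is undefined at k. Reproducible given ``nulls.seed``.
    """
    base = rich_club_curve(matrix, k_values=k_values)
    seeds = np.random.SeedSequence(nulls.seed).spawn(nulls.n_null)
    null_phis = np.full((nulls.n_null, len(base.k_values)), np.nan)
    for r, ss in enumerate(seeds):
        null = rewire_preserving_degree(matrix, nulls, rng=np.random.default_rng(ss))
        null_phis[r] = rich_club_curve(null, k_values=base.k_values).phi
    n_defined = (~np.isnan(null_phis)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_null = np.where(
            n_defined > 0,
            np.nansum(null_phis, axis=0) / np.maximum(n_defined, 1),
            np.nan,
        )
        phi_norm = np.where(
            base.defined & np.isfinite(mean_null) & (mean_null > 0),
            base.phi / np.where(mean_null > 0, mean_null, 1.0),
            np.nan,
        )
    return RichClubCurve(
        k_values=base.k_values,
        phi=base.phi,
        phi_w=base.phi_w,
        defined=base.defined,
        phi_norm=phi_norm,
    )


@dataclass(frozen=True)
class HubSet:
    """Hub nodes of a cohort, ordered by descending averaged degree."""

    method: str  # "sd_rule" | "top_k"
    hubs: tuple[int, ...]
    mean_degrees: np.ndarray  # averaged degree profile over subjects
    threshold: float  # degree cutoff actually applied
    k_top: int | None = None

    def contains(self, node: int) -> bool:
        return node in set(self.hubs)


def identify_hubs(
    cohort: Sequence[SubjectRecord] | Sequence[ConnectivityMatrix],
    method: str = "top_k",
    k_top: int = 13,
    use_strength: bool = False,
) -> HubSet:
    """Hub nodes from the degree profile averaged across all supplied subjects.

    ``top_k`` returns the k_top highest averaged degrees (ties broken by the
    smaller node index); ``sd_rule`` returns nodes whose averaged degree is at
    least one population SD above the profile mean. ``use_strength`` ranks by
    averaged strength instead of binary degree.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must contain at least one subject")
    mats = [s.matrix if isinstance(s, SubjectRecord) else s for s in cohort]
    n = mats[0].n_nodes
    if any(m.n_nodes != n for m in mats):
        raise ValueError("all subjects must share the same node count")
    profiles = np.array(
        [(m.strengths() if use_strength else m.degrees()) for m in mats]
    )
    return hubs_from_profile(profiles.mean(axis=0), method=method, k_top=k_top)


def hubs_from_profile(
    mean_degrees: np.ndarray, method: str = "top_k", k_top: int = 13
) -> HubSet:
    """Apply the hub rule to an averaged degree profile.

    ``sd_rule``: averaged degree at least one population SD above the profile
    mean (inclusive). ``top_k``: the k_top highest, ties broken by the smaller
    node index. Hubs are ordered by descending averaged degree.
    """
    mean_deg = np.asarray(mean_degrees, float)
    n = len(mean_deg)
    order = np.lexsort((np.arange(n), -mean_deg))  # descending degree, low index wins ties
    if method == "top_k":
        if not 1 <= k_top <= n:
            raise ValueError(f"k_top must be in [1, {n}]")
        hubs = tuple(int(i) for i in order[:k_top])
        threshold = float(mean_deg[hubs[-1]])
        return HubSet(method="top_k", hubs=hubs, mean_degrees=mean_deg, threshold=threshold, k_top=k_top)
    if method == "sd_rule":
        thr = float(mean_deg.mean() + mean_deg.std(ddof=0))
        hubs = tuple(int(i) for i in order if mean_deg[i] >= thr)
        return HubSet(method="sd_rule", hubs=hubs, mean_degrees=mean_deg, threshold=thr)
    raise ValueError(f"unknown hub method {method!r}")


def classify_edges(matrix: ConnectivityMatrix, hubs: HubSet) -> pd.DataFrame:
    """Label every present edge rich_club / feeder / local by hub endpoints."""
    hub_set = set(hubs.hubs)
    rows = []
    for i, j, wt in matrix.edge_list():
        n_hub = (i in hub_set) + (j in hub_set)
        cls = ("local", "feeder", "rich_club")[n_hub]
        rows.append((i, j, wt, cls))
    return pd.DataFrame(rows, columns=["i", "j", "weight", "edge_class"])


def count_abnormal_per_node(
    abnormal_edges: Iterable[tuple[int, int, str]], n_nodes: int
) -> pd.DataFrame:
    """Per-node counts of incident abnormal edges, split by direction.

    ``abnormal_edges`` holds (i, j, direction) with direction "increased" or
    "decreased". The sum of all total counts equals twice the edge count.
    """
    inc = np.zeros(n_nodes, dtype=int)
    dec = np.zeros(n_nodes, dtype=int)
    for i, j, direction in abnormal_edges:
        tgt = inc if direction == "increased" else dec
        if direction not in ("increased", "decreased"):
            raise ValueError(f"bad direction {direction!r}")
        tgt[i] += 1
        tgt[j] += 1
    return pd.DataFrame(
        {
            "node": np.arange(n_nodes),
            "n_increased": inc,
            "n_decreased": dec,
            "n_total": inc + dec,
        }
    )
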