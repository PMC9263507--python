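"""Resting-state-network classification of connections.

Each node carries one of the 10 RSN labels from the atlas; a connection is
intra-network when both endpoints share a label and inter-network otherwise.
Summaries count abnormal connections per (network pair, direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .core import NodeAtlas

__all__ = ["RSNConnection", "classify_connection", "summarize_rsn"]


@dataclass(frozen=True)
class RSNConnection:
    """One classified connection between two atlas nodes."""

    edge: tuple[int, int]
    kind: str  # "intra" | "inter"
    networks: tuple[str, str]  # sorted unordered pair of RSN labels
    direction: str | None = None  # "increased" | "decreased" | None


def classify_connection(
    edge: tuple[int, int], atlas: NodeAtlas, direction: str | None = None
) -> RSNConnection:
    """Look up the RSN pair of an edge; symmetric in its endpoints.

    Raises ``IndexError`` for nodes outside the atlas (there is no silent
    OTHER fallback: the bundled atlas assigns every node explicitly).
    """
    i, j = edge
    n = atlas.n_nodes
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"edge {edge} outside atlas of {n} nodes")
    rsn_i, rsn_j = atlas.rsn(i), atlas.rsn(j)
    networks = tuple(sorted((rsn_i, rsn_j)))
    kind = "intra" if rsn_i == rsn_j else "inter"
    return RSNConnection(edge=(i, j), kind=kind, networks=networks, direction=direction)


def summarize_rsn(connections: Iterable[RSNConnection]) -> pd.DataFrame:
    """Contingency counts per (network pair, direction); totals conserved.

    Order-invariant: rows are sorted by (network_a, network_b, direction).
    """
    counts: dict[tuple[str, str, str, str], int] = {}
    for c in connections:
        key = (c.networks[0], c.networks[1], c.kind, c.direction or "unspecified")
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"network_a": a, "network_b": b, "kind": k, "direction": d, "count": n}
        for (a, b, k, d), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["network_a", "network_b", "kind", "direction", "count"])
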