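"""FA-weighted network construction from streamline summary records.

Deterministic whole-brain tractography yields streamlines, each summarized
here by its endpoint regions, per-step FA samples, minimum FA and maximum
inter-step turning angle. Streamlines are kept only if tracking would not
have terminated (min FA >= 0.2 and turning angle < 45 degrees) and both
endpoints land in distinct atlas regions. The FA-based interregional
connection (FABIRC) weight of a region pair is the average FA of the
streamlines linking it — by default the mean over per-streamline mean FA,
optionally the pooled mean over all FA samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core import ConnectivityMatrix

__all__ = [
    "FA_THRESHOLD",
    "ANGLE_THRESHOLD",
    "StreamlineRecord",
    "filter_streamlines",
    "build_fabirc",
    "read_streamlines",
    "write_streamlines",
]

#: Tracking termination thresholds: streamlines with min FA below 0.2 or a
#: turning angle reaching 45 degrees are discarded.
FA_THRESHOLD = 0.2
ANGLE_THRESHOLD = 45.0


@dataclass(frozen=True)
class StreamlineRecord:
    """Summary of one tracked streamline.

    ``region_a``/``region_b`` are 0-based node indices or ``None`` when the
    endpoint fell outside the parcellation. ``min_fa`` defaults to the
    minimum of ``fa_values``.
    """

    region_a: int | None
    region_b: int | None
    fa_values: tuple[float, ...]
    max_turn_angle: float
    min_fa: float | None = None

    def __post_init__(self):
        if not 0 <= self.max_turn_angle <= 180:
            raise ValueError("max_turn_angle must be in [0, 180] degrees")
        if self.min_fa is None:
            object.__setattr__(
                self, "min_fa", min(self.fa_values) if self.fa_values else None
            )
        elif self.fa_values and self.min_fa > min(self.fa_values) + 1e-12:
            raise ValueError("min_fa exceeds the smallest fa_value")

    @property
    def mean_fa(self) -> float:
        return float(np.mean(self.fa_values))


def filter_streamlines(records: Iterable[StreamlineRecord]) -> list[StreamlineRecord]:
    """Apply the tracking-termination and endpoint rules, preserving order.

    Kept records have min FA >= 0.2, max turning angle < 45 degrees, both
    endpoints assigned, and distinct endpoint regions.
    """
    kept = []
    for r in records:
        if r.region_a is None or r.region_b is None:
            continue
        if r.region_a == r.region_b:
            continue
        if not r.fa_values or r.min_fa is None or r.min_fa < FA_THRESHOLD:
            continue
        if r.max_turn_angle >= ANGLE_THRESHOLD:
            continue
        kept.append(r)
    return kept


def build_fabirc(
    records: Sequence[StreamlineRecord],
    n_nodes: int,
    subject_id: str = "",
    pooled: bool = False,
) -> ConnectivityMatrix:
    """Average streamline FA per region pair into a connectivity matrix.

    ``pooled=False`` (default) averages per-streamline mean FA, weighting
    each streamline equally regardless of length; ``pooled=True`` averages
    all FA samples of all streamlines of the pair. Region pairs with no
    streamline get weight 0. Records are assumed already filtered.
    """
    num = np.zeros((n_nodes, n_nodes))
    den = np.zeros((n_nodes, n_nodes))
    for r in records:
        i, j = r.region_a, r.region_b
        if i is None or j is None:
            raise ValueError("unassigned endpoint in supposedly filtered records")
        if not (0 <= i < n_nodes and 0 <= j < n_nodes):
            raise IndexError(f"region index ({i}, {j}) out of range for n_nodes={n_nodes}")
        if pooled:
            num[i, j] += float(np.sum(r.fa_values))
            den[i, j] += len(r.fa_values)
        else:
            num[i, j] += r.mean_fa
            den[i, j] += 1.0
    num = num + num.T
    den = den + den.T
    with np.errstate(invalid="ignore"):
        w = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return ConnectivityMatrix.from_array(w, subject_id=subject_id)


# ---------------------------------------------------------------------------
# TSV round-trip (region_a, region_b, min_fa, max_turn_angle, fa_values)

_UNASSIGNED = -1


def write_streamlines(records: Iterable[StreamlineRecord], path) -> None:
    """Write records as TSV; unassigned endpoints encode as -1."""
    with open(path, "w") as fh:
        fh.write("region_a\tregion_b\tmin_fa\tmax_turn_angle\tfa_values\n")
        for r in records:
            a = _UNASSIGNED if r.region_a is None else r.region_a
            b = _UNASSIGNED if r.region_b is None else r.region_b
            vals = ";".join(f"{v:.17g}" for v in r.fa_values)
            fh.write(f"{a}\t{b}\t{r.min_fa:.17g}\t{r.max_turn_angle:.17g}\t{vals}\n")


def read_streamlines(path) -> list[StreamlineRecord]:
    records = []
    with open(Path(path)) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["region_a", "region_b", "min_fa", "max_turn_angle", "fa_values"]
        if header != expected:
            raise ValueError(f"bad streamline header {header}; expected {expected}")
        for line in fh:
            a_s, b_s, minfa_s, ang_s, vals_s = line.rstrip("\n").split("\t")
            a = None if int(a_s) == _UNASSIGNED else int(a_s)
            b = None if int(b_s) == _UNASSIGNED else int(b_s)
            vals = tuple(float(v) for v in vals_s.split(";")) if vals_s else ()
            records.append(
                StreamlineRecord(
                    region_a=a,
                    region_b=b,
                    fa_values=vals,
                    max_turn_angle=float(ang_s),
                    min_fa=float(minfa_s),
                )
            )
    return records
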