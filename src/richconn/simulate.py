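"""Synthetic FA-weighted connectome cohorts with planted structure.

The generator emulates the study design the analysis expects: 48 HIV+
subjects (split 24 ANI / 24 non-HAND) and 48 healthy controls on a 90-node
AAL parcellation, with 13 planted hub regions (the occipital/subcortical
set reported for such cohorts), FA-like edge weights, group covariates and
six-domain cognitive T-scores.

A single binary topology and per-edge baseline FA field are shared by every
subject; subjects differ by edge-weight noise, a linear age trend, and the
planted group effects. Sharing the topology across groups keeps the binary
degree (hence hub) structure stable and guarantees that, absent planted
effects, groups differ only by noise — which is what makes null-calibration
tests of the statistics meaningful. Every planted effect is recorded in a
ground-truth structure for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    DOMAIN_NAMES,
    ConnectivityMatrix,
    NodeAtlas,
    SubjectRecord,
    load_default_atlas,
    read_atlas,
    read_matrix,
    write_atlas,
    write_matrix,
)
from .construction import StreamlineRecord

__all__ = [
    "DEFAULT_HUB_NODES",
    "EdgeEffect",
    "NodeEffect",
    "CohortConfig",
    "generate_cohort",
    "generate_streamlines",
    "write_cohort",
    "load_cohort",
]

#: Default planted hubs (0-based AAL indices), ordered by planted rank:
#: PUT.R, PUT.L, PCUN.R, PCUN.L, CAL.R, CAU.R, THA.L, SOG.R, CAL.L, SOG.L,
#: CAU.L, MOG.L, CUN.R — the occipital/subcortical hub set such cohorts show.
DEFAULT_HUB_NODES = (73, 72, 67, 66, 43, 71, 76, 49, 42, 48, 70, 50, 45)


@dataclass(frozen=True)
class EdgeEffect:
    """Planted FA shift on one edge for one target group."""

    i: int
    j: int
    delta: float
    group: str  # HIV | HC | ANI | NONHAND


@dataclass(frozen=True)
class NodeEffect:
    """Planted FA shift on all edges incident to one node for one group."""

    node: int
    delta: float
    group: str


def _default_edge_effects() -> tuple[EdgeEffect, ...]:
    """Moderate (|dFA| = 0.04, ~1 subject-SD) effects on the connections the
    study design highlights: occipital/subcortical rich-club edges for the
    HIV group, parietal/occipital ones for the ANI subgroup."""
    return (
        EdgeEffect(72, 48, +0.04, "HIV"),   # PUT.L - SOG.L
        EdgeEffect(72, 73, +0.04, "HIV"),   # PUT.L - PUT.R
        EdgeEffect(76, 43, +0.04, "HIV"),   # THA.L - CAL.R
        EdgeEffect(42, 34, -0.04, "HIV"),   # CAL.L - PCG.L
        EdgeEffect(43, 49, -0.04, "HIV"),   # CAL.R - SOG.R
        EdgeEffect(73, 34, +0.04, "ANI"),   # PUT.R - PCG.L
        EdgeEffect(35, 49, +0.04, "ANI"),   # PCG.R - SOG.R
        EdgeEffect(48, 49, +0.04, "ANI"),   # SOG.L - SOG.R
        EdgeEffect(77, 35, -0.04, "ANI"),   # THA.R - PCG.R
    )


#: Per-subgroup covariate models (age in years; course in months; CD4 in
#: cells/uL): mean, SD of the populations being emulated.
_AGE_MODEL = {"ANI": (31.67, 5.48), "NONHAND": (32.83, 5.92), "HC": (34.52, 6.52)}
_COURSE_MODEL = {"ANI": (40.54, 36.08), "NONHAND": (41.42, 26.71)}
_CD4_MODEL = {"ANI": (581.97, 169.93), "NONHAND": (590.99, 179.82)}
_RATIO_MODEL = {"ANI": (0.79, 0.61), "NONHAND": (0.82, 0.37)}

#: Six-domain T-score models (mean, SD) per subgroup.
_TSCORE_MODEL = {
    "ANI": {
        "verbal_fluency": (41.25, 8.67),
        "attention_working_memory": (38.08, 5.82),
        "executive_function": (49.64, 10.75),
        "learning_delayed_recall": (39.10, 6.83),
        "speed_of_information_processing": (40.35, 8.25),
        "fine_motor_skills": (40.40, 11.60),
    },
    "NONHAND": {
        "verbal_fluency": (48.75, 5.91),
        "attention_working_memory": (44.39, 6.76),
        "executive_function": (59.79, 8.93),
        "learning_delayed_recall": (47.13, 6.43),
        "speed_of_information_processing": (47.83, 8.68),
        "fine_motor_skills": (46.90, 7.58),
    },
}


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the cohort generator (defaults are the study conditions)."""

    n_nodes: int = 90
    n_ani: int = 24
    n_nonhand: int = 24
    n_hc: int = 48
    hub_nodes: tuple[int, ...] = DEFAULT_HUB_NODES
    base_density: float = 0.15
    hub_degree_boost: float = 0.30
    fa_mean: float = 0.45
    fa_baseline_sd: float = 0.05  # between-edge spread of baseline FA
    fa_sd: float = 0.04  # between-subject noise per edge
    baseline_range: tuple[float, float] = (0.25, 0.65)
    weight_clip: tuple[float, float] = (0.05, 0.95)
    effect_edges: tuple[EdgeEffect, ...] = field(default_factory=_default_edge_effects)
    effect_nodes: tuple[NodeEffect, ...] = ()
    age_slope: float = -0.001  # FA units per year of age (leakage into weights)
    sex_slope: float = 0.0  # FA offset for female subjects
    n_female: dict | None = None  # per subgroup; default {'ANI':1,'NONHAND':1,'HC':4}
    with_tscores: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.n_ani, self.n_nonhand, self.n_hc) < 2:
            raise ValueError("group sizes must be >= 2")
        for p in (self.base_density, self.hub_degree_boost):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(not 0 <= h < self.n_nodes for h in self.hub_nodes):
            raise ValueError("hub index outside node range")
        lo, hi = self.baseline_range
        for e in self.effect_edges:
            if hi + max(e.delta, 0) > 1 or lo + min(e.delta, 0) < 0:
                raise ValueError(
                    f"edge effect {e} can push FA outside [0, 1] "
                    f"given baseline range {self.baseline_range}"
                )
        for ne in self.effect_nodes:
            if hi + max(ne.delta, 0) > 1 or lo + min(ne.delta, 0) < 0:
                raise ValueError(f"node effect {ne} can push FA outside [0, 1]")

    @property
    def n_hiv(self) -> int:
        return self.n_ani + self.n_nonhand

    def females(self) -> dict:
        return self.n_female if self.n_female is not None else {"ANI": 1, "NONHAND": 1, "HC": 4}


def _edge_probability(cfg: CohortConfig, hub_mask: np.ndarray) -> np.ndarray:
    n = cfg.n_nodes
    p = np.full((n, n), cfg.base_density)
    p[hub_mask, :] = np.minimum(cfg.base_density + cfg.hub_degree_boost, 0.99)
    p[:, hub_mask] = np.minimum(cfg.base_density + cfg.hub_degree_boost, 0.99)
    hh = np.ix_(hub_mask, hub_mask)
    p[hh] = np.minimum(cfg.base_density + 2 * cfg.hub_degree_boost, 0.99)
    return p


def _applies(effect_group: str, subject_group: str, subgroup: str | None) -> bool:
    if effect_group == subject_group:
        return True
    return effect_group == subgroup


def generate_cohort(config: CohortConfig | None = None) -> tuple[list[SubjectRecord], dict]:
    """Generate the cohort and its ground-truth record.

    Fully reproducible from ``config.seed``; randomness is split into named
    substreams (topology, baseline, covariates, T-scores, subject noise) so
    changing one stage does not perturb the others.
    """
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_topo, rng_base, rng_cov, rng_ts, rng_subj = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    n = cfg.n_nodes
    hub_mask = np.zeros(n, dtype=bool)
    hub_mask[list(cfg.hub_nodes)] = True

    # shared binary topology
    p = _edge_probability(cfg, hub_mask)
    iu, ju = np.triu_indices(n, k=1)
    present = rng_topo.random(len(iu)) < p[iu, ju]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[present], ju[present]] = True
    for e in cfg.effect_edges:  # planted-effect edges must exist
        a, b = min(e.i, e.j), max(e.i, e.j)
        adj[a, b] = True
    adj = adj | adj.T

    # shared baseline FA field on present edges
    lo, hi = cfg.baseline_range
    base = np.zeros((n, n))
    vals = np.clip(rng_base.normal(cfg.fa_mean, cfg.fa_baseline_sd, size=len(iu)), lo, hi)
    upper = adj[iu, ju]
    base[iu[upper], ju[upper]] = vals[upper]
    base = base + base.T

    # subject roster: ANI, NONHAND, then HC, fixed order
    roster: list[tuple[str, str, str | None]] = []
    for idx in range(cfg.n_ani):
        roster.append((f"hiv{idx + 1:03d}", "HIV", "ANI"))
    for idx in range(cfg.n_nonhand):
        roster.append((f"hiv{cfg.n_ani + idx + 1:03d}", "HIV", "NONHAND"))
    for idx in range(cfg.n_hc):
        roster.append((f"hc{idx + 1:03d}", "HC", None))

    # covariates: ages truncated to [18, 55]; sexes as exact per-group counts
    females = cfg.females()
    sex_by_cell: dict[str, list[str]] = {}
    for cell, size in (("ANI", cfg.n_ani), ("NONHAND", cfg.n_nonhand), ("HC", cfg.n_hc)):
        n_f = int(females.get(cell, 0))
        sexes = ["F"] * n_f + ["M"] * (size - n_f)
        rng_cov.shuffle(sexes)
        sex_by_cell[cell] = sexes

    clip_lo, clip_hi = cfg.weight_clip
    subjects: list[SubjectRecord] = []
    cell_counter = {"ANI": 0, "NONHAND": 0, "HC": 0}
    for sid, group, subgroup in roster:
        cell = subgroup or group
        mu, sd = _AGE_MODEL[cell]
        age = float(np.clip(rng_cov.normal(mu, sd), 18, 55))
        sex = sex_by_cell[cell][cell_counter[cell]]
        cell_counter[cell] += 1
        if group == "HIV":
            course = float(max(rng_cov.normal(*_COURSE_MODEL[cell]), 3.0))
            cd4 = float(max(rng_cov.normal(*_CD4_MODEL[cell]), 50.0))
            ratio = float(max(rng_cov.normal(*_RATIO_MODEL[cell]), 0.05))
        else:
            course = cd4 = ratio = None
        tscores = None
        if cfg.with_tscores and cell in _TSCORE_MODEL:
            tscores = {
                d: float(rng_ts.normal(mu_t, sd_t))
                for d, (mu_t, sd_t) in _TSCORE_MODEL[cell].items()
            }

        w = base.copy()
        for e in cfg.effect_edges:
            if _applies(e.group, group, subgroup):
                w[e.i, e.j] += e.delta
                w[e.j, e.i] += e.delta
        for ne in cfg.effect_nodes:
            if _applies(ne.group, group, subgroup):
                w[ne.node, :] += ne.delta * adj[ne.node, :]
                w[:, ne.node] += ne.delta * adj[:, ne.node]
        w += cfg.age_slope * (age - 33.0) + cfg.sex_slope * (1.0 if sex == "F" else 0.0)
        noise = rng_subj.normal(0.0, cfg.fa_sd, size=len(iu))
        w[iu, ju] += noise
        w[ju, iu] = w[iu, ju]
        w = np.clip(w, clip_lo, clip_hi) * adj
        matrix = ConnectivityMatrix.from_array(w, subject_id=sid)
        subjects.append(
            SubjectRecord(
                matrix=matrix,
                group=group,
                subgroup=subgroup,
                age=age,
                sex=sex,
                disease_course=course,
                cd4=cd4,
                cd4_cd8_ratio=ratio,
                domain_tscores=tscores,
            )
        )

    ground_truth = {
        "seed": cfg.seed,
        "n_nodes": n,
        "hub_nodes": list(cfg.hub_nodes),
        "group_sizes": {"HIV": cfg.n_hiv, "HC": cfg.n_hc, "ANI": cfg.n_ani, "NONHAND": cfg.n_nonhand},
        "fa_mean": cfg.fa_mean,
        "base_density": cfg.base_density,
        "hub_degree_boost": cfg.hub_degree_boost,
        "effect_edges": [asdict(e) for e in cfg.effect_edges],
        "effect_nodes": [asdict(ne) for ne in cfg.effect_nodes],
        "age_slope": cfg.age_slope,
        "n_edges": int(adj.sum()) // 2,
    }
    return subjects, ground_truth


# ---------------------------------------------------------------------------
# Streamline simulation


def generate_streamlines(
    pairs: Sequence[tuple[int, int, float, int]],
    seed: int = 0,
    contaminant_fraction: float = 0.0,
    n_steps: tuple[int, int] = (20, 60),
    jitter: float = 0.02,
) -> tuple[list[StreamlineRecord], dict]:
    """Simulate streamline records with known pairwise mean FA.

    ``pairs`` holds (i, j, true_mean_fa, n_streamlines) with true mean FA in
    [0.2, 1). Clean records always satisfy the tracking rules; a
    ``contaminant_fraction`` of extra records each violates exactly one rule
    (low FA, wide turning angle, unassigned endpoint, or a self-loop).
    Returns the records plus ground truth with the contaminant indices.
    """
    rng = np.random.default_rng(seed)
    clean: list[StreamlineRecord] = []
    for i, j, true_fa, n_sl in pairs:
        if not 0.2 <= true_fa < 1:
            raise ValueError(f"true mean FA must be in [0.2, 1), got {true_fa}")
        for _ in range(n_sl):
            length = int(rng.integers(n_steps[0], n_steps[1] + 1))
            vals = np.clip(rng.normal(true_fa, jitter, size=length), 0.2, 0.95)
            angle = float(rng.uniform(5.0, 40.0))
            clean.append(
                StreamlineRecord(region_a=i, region_b=j, fa_values=tuple(vals), max_turn_angle=angle)
            )
    n_contam = int(round(contaminant_fraction * len(clean)))
    contaminants: list[StreamlineRecord] = []
    kinds = ("low_fa", "wide_angle", "unassigned", "self_loop")
    for c in range(n_contam):
        kind = kinds[c % len(kinds)]
        i, j, true_fa, _ = pairs[int(rng.integers(0, len(pairs)))] if pairs else (0, 1, 0.4, 0)
        length = int(rng.integers(n_steps[0], n_steps[1] + 1))
        vals = np.clip(rng.normal(true_fa, jitter, size=length), 0.2, 0.95)
        angle = float(rng.uniform(5.0, 40.0))
        a, b = i, j
        if kind == "low_fa":
            vals[int(rng.integers(0, length))] = 0.1
        elif kind == "wide_angle":
            angle = float(rng.uniform(45.0, 90.0))
        elif kind == "unassigned":
            a = None
        else:  # self_loop
            b = a
        contaminants.append(
            StreamlineRecord(region_a=a, region_b=b, fa_values=tuple(vals), max_turn_angle=angle)
        )
    records = clean + contaminants
    order = rng.permutation(len(records))
    is_contam = np.array([idx >= len(clean) for idx in order])
    records = [records[idx] for idx in order]
    truth = {
        "contaminant_indices": np.nonzero(is_contam)[0].tolist(),
        "n_clean": len(clean),
        "pairs": [list(p) for p in pairs],
    }
    return records, truth


# ---------------------------------------------------------------------------
# Cohort file round-trip (the exact formats the pipeline consumes)


def write_cohort(
    subjects: Sequence[SubjectRecord],
    out_dir,
    atlas: NodeAtlas | None = None,
    ground_truth: dict | None = None,
) -> Path:
    """Emit matrix TSVs, subject table, atlas table and ground_truth.json."""
    out = Path(out_dir)
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    atlas = atlas or load_default_atlas()
    write_atlas(atlas, out / "atlas.tsv")
    rows = []
    for s in subjects:
        write_matrix(s.matrix, out / "matrices" / f"{s.subject_id}.tsv")
        row = {
            "subject_id": s.subject_id,
            "group": s.group,
            "subgroup": s.subgroup or "NA",
            "age": f"{s.age:.6f}",
            "sex": s.sex,
            "disease_course": "NA" if s.disease_course is None else f"{s.disease_course:.6f}",
            "cd4": "NA" if s.cd4 is None else f"{s.cd4:.6f}",
            "cd4_cd8_ratio": "NA" if s.cd4_cd8_ratio is None else f"{s.cd4_cd8_ratio:.6f}",
        }
        for d in DOMAIN_NAMES:
            t = None if s.domain_tscores is None else s.domain_tscores.get(d)
            row[f"tscore_{d}"] = "NA" if t is None else f"{t:.6f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "subjects.tsv", sep="\t", index=False)
    if ground_truth is not None:
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(ground_truth, fh, indent=1, sort_keys=True)
    return out


def load_cohort(in_dir) -> tuple[list[SubjectRecord], NodeAtlas]:
    """Read a cohort directory written by :func:`write_cohort`."""
    src = Path(in_dir)
    atlas = read_atlas(src / "atlas.tsv")
    df = pd.read_csv(src / "subjects.tsv", sep="\t", dtype=str)
    subjects = []
    for _, row in df.iterrows():
        sid = row["subject_id"]
        matrix = read_matrix(src / "matrices" / f"{sid}.tsv", subject_id=sid)

        def opt(key):
            v = row.get(key)
            return None if (v is None or pd.isna(v) or v == "NA") else float(v)

        tscores = {d: opt(f"tscore_{d}") for d in DOMAIN_NAMES}
        tscores = None if any(v is None for v in tscores.values()) else tscores
        subgroup = row["subgroup"]
        subjects.append(
            SubjectRecord(
                matrix=matrix,
                group=row["group"],
                subgroup=None if (pd.isna(subgroup) or subgroup == "NA") else subgroup,
                age=float(row["age"]),
                sex=row["sex"],
                disease_course=opt("disease_course"),
                cd4=opt("cd4"),
                cd4_cd8_ratio=opt("cd4_cd8_ratio"),
                domain_tscores=tscores,
            )
        )
    return subjects, atlas
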