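"""One-command orchestration of the full connectome analysis.

Stages: load (or receive) a cohort -> per-subject nodal and global metrics
-> covariate-adjusted nodal/global group comparisons -> hub identification
per comparison pair -> rich-club edge comparisons -> RSN classification of
abnormal connections -> clinical correlations. All outputs are TSV tables
plus a JSON manifest carrying the config hash, seed and library versions;
rerunning with identical inputs and seed reproduces every table byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    DOMAIN_NAMES,
    NodeAtlas,
    SubjectRecord,
    load_default_atlas,
    select_group,
)
from .metrics import NullModelConfig, global_metrics, nodal_metrics, GlobalMetrics, NodalMetrics
from .richclub import count_abnormal_per_node, identify_hubs
from .rsn import classify_connection, summarize_rsn
from .simulate import load_cohort
from .stats import compare_value_table, edge_comparison, nodal_comparison, partial_correlation

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"

#: Clinical variables screened in the correlation stage.
_CLINICAL_VARS = ("disease_course", "cd4", "cd4_cd8_ratio") + tuple(
    f"tscore_{d}" for d in DOMAIN_NAMES
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run (YAML-serializable)."""

    input_dir: str | None = None
    out_dir: str = "run_out"
    comparisons: tuple[tuple[str, str], ...] = (("HIV", "HC"), ("ANI", "NONHAND"))
    mode: str = "weighted"
    smallworld: bool = True
    n_null: int = 100
    rewires_per_edge: int = 10
    hub_method: str = "top_k"
    k_top: int = 13
    alpha: float = 0.05
    welch: bool = False
    correlation_group: str = "HIV"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "comparisons" in raw:
            raw["comparisons"] = tuple(tuple(pair) for pair in raw["comparisons"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["comparisons"] = [list(p) for p in self.comparisons]
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _clinical_value(subject: SubjectRecord, var: str) -> float | None:
    if var.startswith("tscore_"):
        if subject.domain_tscores is None:
            return None
        return subject.domain_tscores.get(var[len("tscore_"):])
    return getattr(subject, var)


def _stage(name: str):
    """Decorator-ish context: re-raise any stage failure naming the stage."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_pipeline(
    config: RunConfig,
    subjects: list[SubjectRecord] | None = None,
    atlas: NodeAtlas | None = None,
) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        if subjects is None:
            if config.input_dir is None:
                raise ValueError("either subjects or config.input_dir is required")
            subjects, atlas = load_cohort(config.input_dir)
        if atlas is None:
            atlas = load_default_atlas()
        labels = atlas.labels
        for pair in config.comparisons:
            for g in pair:
                if not select_group(subjects, g):
                    raise ValueError(f"group {g!r} has no subjects")

    with _stage("metrics"):
        nodal_by_subject: dict[str, NodalMetrics] = {}
        global_by_subject: dict[str, GlobalMetrics] = {}
        tidy_rows = []
        for idx, s in enumerate(subjects):
            nm = nodal_metrics(s.matrix, mode=config.mode)
            nodal_by_subject[s.subject_id] = nm
            nulls = None
            if config.smallworld:
                sub_seed = int(np.random.SeedSequence([config.seed, 700 + idx]).generate_state(1)[0])
                nulls = NullModelConfig(
                    n_null=config.n_null,
                    rewires_per_edge=config.rewires_per_edge,
                    seed=sub_seed,
                )
            gm = global_metrics(s.matrix, nulls=nulls, mode=config.mode)
            global_by_subject[s.subject_id] = gm
            for metric, vals in nm.as_dict().items():
                for node, v in enumerate(vals):
                    tidy_rows.append(
                        (s.subject_id, node + 1, labels[node], metric, config.mode, "raw", v)
                    )
        _write(
            pd.DataFrame(
                tidy_rows,
                columns=["subject_id", "node", "label", "metric", "mode", "sparsity", "value"],
            ),
            out / "metrics_nodal.tsv",
        )
        grows = [
            {"subject_id": sid, **gm.as_dict()} for sid, gm in global_by_subject.items()
        ]
        _write(pd.DataFrame(grows), out / "metrics_global.tsv")

    correlation_metric_targets: list[tuple[str, int]] = []
    correlation_edge_targets: list[tuple[int, int]] = []

    for group_a, group_b in config.comparisons:
        pair_tag = f"{group_a}_vs_{group_b}"
        ca = select_group(subjects, group_a)
        cb = select_group(subjects, group_b)

        with _stage(f"nodal_comparison[{pair_tag}]"):
            nodal_cmp = nodal_comparison(
                ca,
                cb,
                alpha=config.alpha,
                mode=config.mode,
                precomputed=nodal_by_subject,
                labels=labels,
                welch=config.welch,
            )
            table = nodal_cmp.copy()
            table["node"] = table["node"] + 1  # 1-based AAL in reports
            _write(
                table[
                    ["metric", "node", "label", "t", "p", "p_bonf", "direction",
                     "significant_raw", "significant_corrected"]
                ],
                out / f"compare_nodal_{pair_tag}.tsv",
            )

        with _stage(f"global_comparison[{pair_tag}]"):
            gnames = ["cp", "lp", "eglob", "strength"] + (
                ["gamma", "lam", "sigma"] if config.smallworld else []
            )
            va = np.array([[global_by_subject[s.subject_id].as_dict()[g] for g in gnames] for s in ca])
            vb = np.array([[global_by_subject[s.subject_id].as_dict()[g] for g in gnames] for s in cb])
            gcmp = compare_value_table(
                va, vb,
                (np.array([s.age for s in ca]), np.array([float(s.sex_code) for s in ca])),
                (np.array([s.age for s in cb]), np.array([float(s.sex_code) for s in cb])),
                m_family=len(gnames),
                alpha=config.alpha,
                welch=config.welch,
            )
            gcmp["metric"] = gnames
            _write(
                gcmp[["metric", "t", "p", "p_bonf", "direction", "significant_raw", "significant_corrected"]],
                out / f"compare_global_{pair_tag}.tsv",
            )

        with _stage(f"hubs[{pair_tag}]"):
            hubs = identify_hubs(ca + cb, method=config.hub_method, k_top=config.k_top)
            hub_table = pd.DataFrame(
                {
                    "rank": np.arange(1, len(hubs.hubs) + 1),
                    "node": [h + 1 for h in hubs.hubs],
                    "label": [labels[h] for h in hubs.hubs],
                    "mean_degree": [hubs.mean_degrees[h] for h in hubs.hubs],
                    "group_pair": pair_tag,
                }
            )
            _write(hub_table, out / f"hubs_{pair_tag}.tsv")

        with _stage(f"richclub_edges[{pair_tag}]"):
            # hub-hub pairs present in at least one subject of either group
            n_nodes = atlas.n_nodes
            union = np.zeros((n_nodes, n_nodes), dtype=bool)
            for s in ca + cb:
                union |= s.matrix.weights > 0
            hub_list = sorted(hubs.hubs)
            rc_edges = [
                (i, j)
                for ai, i in enumerate(hub_list)
                for j in hub_list[ai + 1:]
                if union[i, j]
            ]
            ecmp = edge_comparison(ca, cb, rc_edges, alpha=config.alpha, welch=config.welch)
            if len(ecmp):
                ecmp = ecmp.copy()
                conns = [
                    classify_connection((int(r.i), int(r.j)), atlas, direction=r.direction)
                    for r in ecmp.itertuples()
                ]
                ecmp["label_i"] = [labels[int(i)] for i in ecmp["i"]]
                ecmp["label_j"] = [labels[int(j)] for j in ecmp["j"]]
                ecmp["network_a"] = [c.networks[0] for c in conns]
                ecmp["network_b"] = [c.networks[1] for c in conns]
                ecmp["kind"] = [c.kind for c in conns]
                ecmp["node_i"] = ecmp["i"] + 1
                ecmp["node_j"] = ecmp["j"] + 1
            _write(
                ecmp.drop(columns=["i", "j"], errors="ignore"),
                out / f"richclub_edges_{pair_tag}.tsv",
            )

        with _stage(f"abnormal_connections[{pair_tag}]"):
            abnormal = ecmp[ecmp["significant_raw"]] if len(ecmp) else ecmp
            ab_edges = [
                (int(r.node_i) - 1, int(r.node_j) - 1, r.direction)
                for r in abnormal.itertuples()
            ] if len(abnormal) else []
            counts = count_abnormal_per_node(ab_edges, atlas.n_nodes)
            counts["label"] = [labels[i] for i in counts["node"]]
            counts["node"] = counts["node"] + 1
            _write(
                counts[["node", "label", "n_increased", "n_decreased", "n_total"]],
                out / f"abnormal_nodes_{pair_tag}.tsv",
            )
            conns = [
                classify_connection((i, j), atlas, direction=d) for (i, j, d) in ab_edges
            ]
            _write(summarize_rsn(conns), out / f"rsn_summary_{pair_tag}.tsv")

        if group_a == config.correlation_group:
            sig = nodal_cmp[nodal_cmp["significant_raw"]]
            correlation_metric_targets = [
                (str(r.metric), int(r.node)) for r in sig.itertuples()
            ]
            correlation_edge_targets = (
                [(int(r.node_i) - 1, int(r.node_j) - 1) for r in abnormal.itertuples()]
                if len(abnormal)
                else []
            )

    with _stage("correlations"):
        cg = select_group(subjects, config.correlation_group)
        rows = []
        for var in _CLINICAL_VARS:
            vals = [_clinical_value(s, var) for s in cg]
            mask = [v is not None for v in vals]
            sub = [s for s, m in zip(cg, mask) if m]
            y = np.array([v for v, m in zip(vals, mask) if m], float)
            if len(sub) < 6:
                continue
            covs = np.column_stack(
                [[s.age for s in sub], [float(s.sex_code) for s in sub]]
            )
            for metric, node in correlation_metric_targets:
                x = np.array(
                    [getattr(nodal_by_subject[s.subject_id], metric)[node] for s in sub]
                )
                r, p = partial_correlation(x, y, covs)
                rows.append(
                    {"variable": var, "target": f"{metric}[{labels[node]}]",
                     "r": r, "p": p, "n": len(sub), "significant": bool(p < config.alpha) if np.isfinite(p) else False}
                )
            for (i, j) in correlation_edge_targets:
                x = np.array([s.matrix.weights[i, j] for s in sub])
                r, p = partial_correlation(x, y, covs)
                rows.append(
                    {"variable": var, "target": f"edge[{labels[i]}-{labels[j]}]",
                     "r": r, "p": p, "n": len(sub), "significant": bool(p < config.alpha) if np.isfinite(p) else False}
                )
        _write(
            pd.DataFrame(rows, columns=["variable", "target", "r", "p", "n", "significant"]),
            out / "correlations.tsv",
        )

    with _stage("manifest"):
        manifest = {
            "config": config.to_dict(),
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "n_subjects": len(subjects),
            "versions": {
                "richconn": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    return out
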