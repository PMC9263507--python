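"""Covariate-adjusted group comparisons, correction, ANI classification.

Group differences in nodal metrics and rich-club edge weights are tested
with pooled-variance two-sample t-tests on age/sex-adjusted values. The
adjustment regresses the values on [intercept, age, sex] pooled across both
groups (so the group contrast itself is not absorbed) and tests the
residuals; Welch's test is available as a variant. Bonferroni correction
uses the node count as the family within each metric.

Partial correlations residualize both variables on the covariates and take
the Pearson correlation of the residuals, with p from a t distribution on
n - 2 - q degrees of freedom.

The ANI pattern classifier applies the Frascati-style rule: T-scores at
least one SD below the adjusted mean (inclusive) in two or more of the six
cognitive domains.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import DOMAIN_NAMES, SubjectRecord
from .metrics import NodalMetrics, nodal_metrics

__all__ = [
    "DegenerateResultWarning",
    "adjust_covariates",
    "two_sample_t",
    "bonferroni",
    "compare_value_table",
    "nodal_comparison",
    "edge_comparison",
    "classify_ani",
    "partial_correlation",
]

logger = logging.getLogger(__name__)


class DegenerateResultWarning(UserWarning):
    """A test or correlation was degenerate (zero variance) and flagged."""


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != n:
        c = c.T
    return np.column_stack([np.ones(n), c])


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the first column that adds no rank
        for col in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : col + 1]) <= np.linalg.matrix_rank(X[:, :col]):
                name = names[col - 1] if col - 1 < len(names) else f"col{col}"
                raise np.linalg.LinAlgError(
                    f"covariate {name!r} is collinear with the preceding design columns"
                )
        raise np.linalg.LinAlgError("rank-deficient covariate design")


def adjust_covariates(
    values: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    names: Sequence[str] = ("age", "sex"),
) -> np.ndarray:
    """OLS residuals of values on [intercept, age, sex].

    Fit pooled across both groups so planted group effects survive into the
    residuals. ``sex`` is coded 0/1. Collinear covariates raise
    ``numpy.linalg.LinAlgError`` naming the offending column.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    if n < 3 + 1:  # need more subjects than the 3 design columns
        raise ValueError("need at least covariate count + 2 subjects")
    X = np.column_stack([np.ones(n), np.asarray(age, float), np.asarray(sex, float)])
    _check_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def two_sample_t(group_a: np.ndarray, group_b: np.ndarray, welch: bool = False) -> tuple[float, float]:
    """Two-sided pooled-variance t-test, signed A minus B.

    Zero pooled variance is flagged degenerate and returns (0.0, 1.0) by
    convention. ``welch=True`` switches to the unequal-variance test.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() != b.mean():
            warnings.warn(
                "zero pooled variance with unequal means; degenerate t-test",
                DegenerateResultWarning,
                stacklevel=2,
            )
        return (0.0, 1.0)
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return (float(t), float(p))


def bonferroni(p: float, m: int) -> float:
    """min(1, m * p)."""
    return float(min(1.0, m * p))


def _covariates_of(cohort: Sequence[SubjectRecord]) -> tuple[np.ndarray, np.ndarray]:
    ages = np.array([s.age for s in cohort], float)
    sexes = np.array([s.sex_code for s in cohort], float)
    return ages, sexes


def compare_value_table(
    values_a: np.ndarray,
    values_b: np.ndarray,
    cov_a: tuple[np.ndarray, np.ndarray] | None,
    cov_b: tuple[np.ndarray, np.ndarray] | None,
    m_family: int,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Columnwise adjusted t-tests of (n_a x m) vs (n_b x m) value arrays.

    Covariate adjustment is pooled over both groups per column. Returns one
    row per column with t, p, Bonferroni-corrected p (family ``m_family``),
    direction and significance flags.
    """
    va = np.atleast_2d(np.asarray(values_a, float))
    vb = np.atleast_2d(np.asarray(values_b, float))
    # columns with no real variation (e.g. binary degree when every subject
    # shares the topology) are degenerate before adjustment and stay so:
    # residualizing a constant leaves only floating-point noise, which must
    # not reach a t-test.
    pooled_raw = np.vstack([va, vb])
    spread = pooled_raw.max(axis=0) - pooled_raw.min(axis=0)
    scale = np.maximum(1.0, np.abs(pooled_raw).max(axis=0))
    degenerate_cols = spread <= 1e-9 * scale
    if cov_a is not None and cov_b is not None:
        age = np.concatenate([cov_a[0], cov_b[0]])
        sex = np.concatenate([cov_a[1], cov_b[1]])
        pooled = np.vstack([va, vb])
        resid = adjust_covariates(pooled, age, sex)
        ra, rb = resid[: len(va)], resid[len(va):]
    else:
        ra, rb = va, vb
    rows = []
    for col in range(va.shape[1]):
        if degenerate_cols[col]:
            t, p = 0.0, 1.0
        else:
            t, p = two_sample_t(ra[:, col], rb[:, col], welch=welch)
        p_bonf = bonferroni(p, m_family)
        rows.append(
            {
                "unit": col,
                "t": t,
                "p": p,
                "p_bonf": p_bonf,
                "direction": "increased" if t > 0 else "decreased",
                "significant_raw": p < alpha,
                "significant_corrected": p_bonf < alpha,
            }
        )
    return pd.DataFrame(rows)


def nodal_comparison(
    cohort_a: Sequence[SubjectRecord],
    cohort_b: Sequence[SubjectRecord],
    metrics: Sequence[str] = ("dc", "bc", "nlp", "ncc", "ne"),
    alpha: float = 0.05,
    mode: str = "weighted",
    adjust: bool = True,
    precomputed: Mapping[str, NodalMetrics] | None = None,
    labels: Sequence[str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Per node x metric covariate-adjusted group comparison.

    Bonferroni family size is the node count within each metric. Pass
    ``precomputed`` (subject_id -> NodalMetrics) to reuse metric computations.
    Missing covariates raise rather than silently dropping subjects.
    """
    if not cohort_a or not cohort_b:
        raise ValueError("both cohorts must be non-empty")
    n_nodes = cohort_a[0].matrix.n_nodes
    if any(s.matrix.n_nodes != n_nodes for s in list(cohort_a) + list(cohort_b)):
        raise ValueError("node count mismatch across subjects")

    def metric_rows(cohort):
        out = {}
        for s in cohort:
            nm = None
            if precomputed is not None:
                nm = precomputed.get(s.subject_id)
            if nm is None:
                nm = nodal_metrics(s.matrix, mode=mode)
            out[s.subject_id] = nm
        return out

    nm_a = metric_rows(cohort_a)
    nm_b = metric_rows(cohort_b)
    cov_a = _covariates_of(cohort_a) if adjust else None
    cov_b = _covariates_of(cohort_b) if adjust else None
    frames = []
    for metric in metrics:
        va = np.array([getattr(nm_a[s.subject_id], metric) for s in cohort_a])
        vb = np.array([getattr(nm_b[s.subject_id], metric) for s in cohort_b])
        # infinite path lengths (isolated nodes) cannot enter a t-test
        bad = ~np.isfinite(va).all(axis=0) | ~np.isfinite(vb).all(axis=0)
        va = np.where(np.isfinite(va), va, 0.0)
        vb = np.where(np.isfinite(vb), vb, 0.0)
        df = compare_value_table(va, vb, cov_a, cov_b, m_family=n_nodes, alpha=alpha, welch=welch)
        df.insert(0, "metric", metric)
        df = df.rename(columns={"unit": "node"})
        df["label"] = (
            [labels[i] for i in df["node"]] if labels is not None else df["node"].astype(str)
        )
        if bad.any():
            df.loc[df["node"].isin(np.nonzero(bad)[0]), ["significant_raw", "significant_corrected"]] = False
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def edge_comparison(
    cohort_a: Sequence[SubjectRecord],
    cohort_b: Sequence[SubjectRecord],
    edges: Sequence[tuple[int, int]],
    alpha: float = 0.05,
    adjust: bool = True,
    welch: bool = False,
) -> pd.DataFrame:
    """Covariate-adjusted t-tests of per-subject edge weights.

    Edges absent (zero weight) in every subject of both groups are skipped
    with a log entry. Direction follows the sign of t: positive = increased
    (enhanced connection) in group A.
    """
    if not edges:
        return pd.DataFrame(
            columns=["i", "j", "t", "p", "p_bonf", "direction", "significant_raw", "significant_corrected"]
        )
    wa = np.array([[s.matrix.weights[i, j] for (i, j) in edges] for s in cohort_a])
    wb = np.array([[s.matrix.weights[i, j] for (i, j) in edges] for s in cohort_b])
    keep = (wa > 0).any(axis=0) | (wb > 0).any(axis=0)
    skipped = [edges[idx] for idx in np.nonzero(~keep)[0]]
    for e in skipped:
        logger.info("edge %s absent in all subjects of both groups; skipped", e)
    kept_edges = [e for e, k in zip(edges, keep) if k]
    if not kept_edges:
        return pd.DataFrame(
            columns=["i", "j", "t", "p", "p_bonf", "direction", "significant_raw", "significant_corrected"]
        )
    cov_a = _covariates_of(cohort_a) if adjust else None
    cov_b = _covariates_of(cohort_b) if adjust else None
    df = compare_value_table(
        wa[:, keep], wb[:, keep], cov_a, cov_b, m_family=len(kept_edges), alpha=alpha, welch=welch
    )
    df["i"] = [e[0] for e in kept_edges]
    df["j"] = [e[1] for e in kept_edges]
    return df[["i", "j", "t", "p", "p_bonf", "direction", "significant_raw", "significant_corrected"]]


def classify_ani(
    domain_tscores: Mapping[str, float],
    adjusted_means: Mapping[str, float],
    sds: Mapping[str, float],
) -> str:
    """Frascati-style pattern rule on six domain T-scores.

    Returns "ANI_pattern" iff at least two domains score at or below the
    adjusted mean minus one SD (boundary inclusive), else "normal". The
    daily-living criterion is an input flag upstream, not computed here.
    Missing domains raise ``KeyError``.
    """
    n_impaired = 0
    for name in DOMAIN_NAMES:
        if name not in domain_tscores:
            raise KeyError(f"missing domain T-score: {name!r}")
        if name not in adjusted_means or name not in sds:
            raise KeyError(f"missing normative mean/SD for domain {name!r}")
        if domain_tscores[name] <= adjusted_means[name] - sds[name]:
            n_impaired += 1
    return "ANI_pattern" if n_impaired >= 2 else "normal"


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Pearson correlation of covariate-residualized x and y.

    ``covariates`` is an (n x q) array (or None for a plain Pearson
    correlation). p comes from a t distribution with n - 2 - q degrees of
    freedom. Zero-variance residuals are flagged degenerate -> (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    q = 0
    if covariates is not None and np.size(covariates) > 0:
        C = np.atleast_2d(np.asarray(covariates, float))
        if C.shape[0] != n:
            C = C.T
        q = C.shape[1]
    if n <= q + 2:
        raise ValueError("need n > covariate count + 2")
    X = _design(covariates if q else None, n)
    bx, *_ = np.linalg.lstsq(X, x, rcond=None)
    by, *_ = np.linalg.lstsq(X, y, rcond=None)
    rx = x - X @ bx
    ry = y - X @ by
    sx, sy = rx.std(), ry.std()
    # residual variance that is pure floating-point noise counts as zero
    tol_x = 1e-10 * max(1.0, float(np.abs(x).max()))
    tol_y = 1e-10 * max(1.0, float(np.abs(y).max()))
    if sx <= tol_x or sy <= tol_y:
        warnings.warn(
            "zero-variance residuals in partial correlation",
            DegenerateResultWarning,
            stacklevel=2,
        )
        return (np.nan, np.nan)
    r = float(np.dot(rx - rx.mean(), ry - ry.mean()) / (n * rx.std() * ry.std()))
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2 - q
    if abs(r) == 1.0:
        return (r, 0.0)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2 * sps.t.sf(abs(t), df))
    return (r, p)
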