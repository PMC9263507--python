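"""Core domain types and I/O for FA-weighted structural connectomes.

The atomic object is a :class:`ConnectivityMatrix`: a symmetric, non-negative,
zero-diagonal N x N array of FA-based interregional connection weights, one
per subject. A :class:`NodeAtlas` maps the N nodes (AAL-90 by default) to
region labels, hemispheres and resting-state networks; a
:class:`SubjectRecord` bundles a matrix with group membership, covariates,
clinical variables and cognitive-domain T-scores.

All files are plain delimited text: matrices are header-less N-row grids
(TSV by default, CSV accepted); atlas and subject tables are TSV with a named
header row. Node indices are 0-based internally; file formats carry 1-based
AAL indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RSN_VOCAB",
    "DOMAIN_NAMES",
    "GROUPS",
    "MatrixFormatError",
    "AtlasFormatError",
    "AsymmetryWarning",
    "ConnectivityMatrix",
    "AtlasEntry",
    "NodeAtlas",
    "SubjectRecord",
    "SparsityConfig",
    "read_matrix",
    "write_matrix",
    "apply_sparsity",
    "read_atlas",
    "load_default_atlas",
    "select_group",
]

#: The 10 resting-state-network labels used to parcel the AAL-90 regions.
RSN_VOCAB = frozenset(
    {"DMN", "SN", "VN", "SMN", "PAC", "EXN", "ORB", "OLF", "THA", "OTHER"}
)

#: Canonical names of the six cognitive domains covered by the NP battery.
DOMAIN_NAMES = (
    "verbal_fluency",
    "attention_working_memory",
    "executive_function",
    "learning_delayed_recall",
    "speed_of_information_processing",
    "fine_motor_skills",
)

#: Recognised group labels. ANI and NONHAND are subgroups of HIV.
GROUPS = ("HIV", "HC", "ANI", "NONHAND")

_SYMMETRY_WARN_TOL = 1e-6
_SYMMETRY_TOL = 1e-12


class MatrixFormatError(ValueError):
    """A matrix file or array does not satisfy the format contract."""


class AtlasFormatError(ValueError):
    """An atlas table violates its invariants (duplicates, bad vocabulary)."""


class AsymmetryWarning(UserWarning):
    """Raised when an input matrix is asymmetric beyond 1e-6 and is averaged."""


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A validated symmetric FA-weighted adjacency matrix for one subject.

    ``weights[i, j]`` is the mean FA of streamlines linking regions i and j
    (unitless, typically in [0, 1]); 0 means no connection. The constructor
    does not validate — use :meth:`from_array` for untrusted input.
    """

    weights: np.ndarray
    subject_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def from_array(cls, array, subject_id: str = "") -> "ConnectivityMatrix":
        """Validate and canonicalize an array into a ConnectivityMatrix.

        The array is symmetrized by averaging with its transpose (asymmetry
        above 1e-6 emits an :class:`AsymmetryWarning`) and the diagonal is
        zeroed. Negative entries, NaNs and non-square shapes are rejected.
        """
        a = np.asarray(array, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise MatrixFormatError(f"matrix must be square, got shape {a.shape}")
        if a.shape[0] < 2:
            raise MatrixFormatError("matrix needs at least 2 nodes")
        if np.isnan(a).any():
            raise ValueError("matrix contains NaN entries")
        if (a < 0).any():
            raise ValueError("matrix contains negative entries")
        asym = np.abs(a - a.T).max()
        if asym > _SYMMETRY_WARN_TOL:
            warnings.warn(
                f"matrix {subject_id or '<unnamed>'} asymmetric by {asym:.3g}; "
                "averaging with transpose",
                AsymmetryWarning,
                stacklevel=2,
            )
        w = (a + a.T) / 2.0
        np.fill_diagonal(w, 0.0)
        w.setflags(write=False)
        return cls(weights=w, subject_id=subject_id)

    # -- derived views -----------------------------------------------------

    def binary(self) -> np.ndarray:
        """0/1 adjacency (presence of any connection)."""
        return (self.weights > 0).astype(float)

    def degrees(self) -> np.ndarray:
        """Binary degree of every node."""
        return (self.weights > 0).sum(axis=1).astype(float)

    def strengths(self) -> np.ndarray:
        """Sum of connection weights per node."""
        return self.weights.sum(axis=1)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Present edges as (i, j, weight) with i < j."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        mask = self.weights[iu, ju] > 0
        return list(zip(iu[mask].tolist(), ju[mask].tolist(), self.weights[iu[mask], ju[mask]].tolist()))

    @property
    def n_edges(self) -> int:
        return int((self.weights > 0).sum()) // 2

    def validate(self) -> None:
        """Assert the post-validation invariants (cheap; used in tests/pipeline)."""
        w = self.weights
        assert w.shape[0] == w.shape[1] >= 2
        assert np.abs(w - w.T).max() <= _SYMMETRY_TOL
        assert np.all(np.diag(w) == 0)
        assert np.all(w >= 0)


def read_matrix(path, delimiter: str | None = None, subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a header-less N x N grid of weights from delimited text.

    ``delimiter=None`` sniffs: comma if the first line contains one, else any
    whitespace (covers TSV). Non-square grids raise
    :class:`MatrixFormatError`; NaN or negative entries raise ``ValueError``.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = "," if "," in first else None
    try:
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise MatrixFormatError(f"could not parse {path}: {exc}") from exc
    sid = subject_id if subject_id is not None else path.stem
    return ConnectivityMatrix.from_array(arr, subject_id=sid)


def write_matrix(matrix: ConnectivityMatrix, path, delimiter: str = "\t") -> None:
    """Write the weight grid as delimited text at fixed precision.

    The format round-trips bit-comparably through :func:`read_matrix` for
    weights representable in 17 significant digits.
    """
    np.savetxt(path, matrix.weights, fmt="%.17g", delimiter=delimiter)


def apply_sparsity(matrix: ConnectivityMatrix, sparsity: float) -> ConnectivityMatrix:
    """Keep the ``round(sparsity * N(N-1)/2)`` strongest edges, zero the rest.

    Ties at the cutoff are broken in favour of the lexicographically smaller
    (i, j) pair, which makes thresholding idempotent and edge sets monotone
    across sparsity levels. Weights of retained edges are unchanged.
    """
    if not 0 < sparsity < 1:
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    n = matrix.n_nodes
    n_possible = n * (n - 1) // 2
    m_keep = int(round(sparsity * n_possible))
    if m_keep == 0:
        raise ValueError(f"sparsity {sparsity} retains zero edges at N={n}")
    edges = matrix.edge_list()
    if m_keep >= len(edges):
        return matrix
    edges.sort(key=lambda e: (-e[2], e[0], e[1]))
    w = np.zeros_like(matrix.weights)
    for i, j, wt in edges[:m_keep]:
        w[i, j] = w[j, i] = wt
    return ConnectivityMatrix.from_array(w, subject_id=matrix.subject_id)


# ---------------------------------------------------------------------------
# Atlas


@dataclass(frozen=True)
class AtlasEntry:
    index: int  # 0-based internal node index
    label: str  # e.g. "CAL.L"
    hemisphere: str  # "L" or "R"
    rsn: str  # one of RSN_VOCAB
    alt_rsn: str | None = None  # optional alternative assignment


@dataclass(frozen=True)
class NodeAtlas:
    """Ordered region table for the parcellation (AAL-90 by default)."""

    entries: tuple[AtlasEntry, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    def label(self, index: int) -> str:
        return self.entries[index].label

    def index(self, label: str) -> int:
        return self._label_map()[label]

    def rsn(self, node) -> str:
        """RSN of a node given by 0-based index or label."""
        if isinstance(node, str):
            node = self.index(node)
        return self.entries[node].rsn

    def _label_map(self) -> dict[str, int]:
        return {e.label: e.index for e in self.entries}

    @classmethod
    def from_entries(cls, entries: Iterable[AtlasEntry]) -> "NodeAtlas":
        entries = tuple(entries)
        indices = [e.index for e in entries]
        if indices != list(range(len(entries))):
            raise AtlasFormatError("atlas indices must be 0..N-1 without gaps")
        labels = [e.label for e in entries]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise AtlasFormatError(f"duplicate atlas labels: {dupes}")
        for e in entries:
            if e.rsn not in RSN_VOCAB:
                raise AtlasFormatError(f"unknown RSN token {e.rsn!r} for {e.label}")
            if e.hemisphere not in ("L", "R"):
                raise AtlasFormatError(f"hemisphere must be L or R, got {e.hemisphere!r}")
        return cls(entries=entries)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with 1-based AAL indices (file convention)."""
        return pd.DataFrame(
            {
                "index": [e.index + 1 for e in self.entries],
                "label": [e.label for e in self.entries],
                "hemisphere": [e.hemisphere for e in self.entries],
                "rsn": [e.rsn for e in self.entries],
                "alt_rsn": [e.alt_rsn or "-" for e in self.entries],
            }
        )


def read_atlas(path) -> NodeAtlas:
    """Read a TSV atlas table (columns index,label,hemisphere,rsn[,alt_rsn]).

    The file's ``index`` column holds 1-based AAL numbers; internally the
    atlas is 0-based.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"index", "label", "hemisphere", "rsn"}
    missing = required - set(df.columns)
    if missing:
        raise AtlasFormatError(f"atlas table missing columns: {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        alt = row.get("alt_rsn")
        alt = None if (alt is None or pd.isna(alt) or alt == "-") else str(alt)
        entries.append(
            AtlasEntry(
                index=int(row["index"]) - 1,
                label=str(row["label"]),
                hemisphere=str(row["hemisphere"]),
                rsn=str(row["rsn"]),
                alt_rsn=alt,
            )
        )
    return NodeAtlas.from_entries(entries)


def load_default_atlas() -> NodeAtlas:
    """The bundled AAL-90 atlas with the reconstructed RSN assignment."""
    with resources.as_file(
        resources.files("richconn.data").joinpath("aal90_rsn.tsv")
    ) as p:
        return read_atlas(p)


def write_atlas(atlas: NodeAtlas, path) -> None:
    atlas.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Subjects


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: connectome plus covariates and clinical variables.

    ``group`` is HIV or HC; for HIV subjects ``subgroup`` flags the ANI /
    NONHAND subset membership so the two comparison levels never double-count
    a subject within one comparison.
    """

    matrix: ConnectivityMatrix
    group: str
    age: float
    sex: str  # "M" or "F"
    subgroup: str | None = None  # "ANI" | "NONHAND" for HIV subjects
    disease_course: float | None = None  # months
    cd4: float | None = None  # cells/uL
    cd4_cd8_ratio: float | None = None
    domain_tscores: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.group not in ("HIV", "HC"):
            raise ValueError(f"group must be HIV or HC, got {self.group!r}")
        if self.subgroup not in (None, "ANI", "NONHAND"):
            raise ValueError(f"bad subgroup {self.subgroup!r}")
        if self.subgroup is not None and self.group != "HIV":
            raise ValueError("only HIV subjects carry an ANI/NONHAND subgroup")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.domain_tscores is not None:
            for name, t in self.domain_tscores.items():
                if not np.isfinite(t):
                    raise ValueError(f"non-finite T-score for domain {name!r}")

    @property
    def subject_id(self) -> str:
        return self.matrix.subject_id

    @property
    def sex_code(self) -> int:
        """Numeric sex coding used by covariate adjustment (M=0, F=1)."""
        return 0 if self.sex == "M" else 1


def select_group(cohort: Sequence[SubjectRecord], name: str) -> list[SubjectRecord]:
    """Subjects belonging to a named group or subgroup.

    HIV/HC select on ``group``; ANI/NONHAND select HIV subjects by
    ``subgroup`` (a subset of the HIV group, never overlapping each other).
    """
    if name in ("HIV", "HC"):
        return [s for s in cohort if s.group == name]
    if name in ("ANI", "NONHAND"):
        return [s for s in cohort if s.subgroup == name]
    raise ValueError(f"unknown group {name!r}; expected one of {GROUPS}")


@dataclass(frozen=True)
class SparsityConfig:
    """Optional sparsity-threshold grid with an aggregation rule.

    The default analysis runs on the raw weighted matrix; when a grid is
    supplied, metrics are computed per threshold and either reported
    per-threshold or integrated (AUC, trapezoidal over sparsity).
    """

    sparsities: tuple[float, ...] = ()
    aggregate: str = "auc"  # "per_threshold" | "auc"

    def __post_init__(self):
        s = self.sparsities
        if any(not 0 < x < 1 for x in s):
            raise ValueError("sparsities must lie in (0, 1)")
        if list(s) != sorted(set(s)):
            raise ValueError("sparsities must be strictly increasing")
        if self.aggregate not in ("per_threshold", "auc"):
            raise ValueError(f"unknown aggregate {self.aggregate!r}")

    @classmethod
    def default_grid(cls) -> "SparsityConfig":
        """0.10 to 0.34 in steps of 0.01, AUC-aggregated."""
        return cls(sparsities=tuple(np.round(np.arange(0.10, 0.3401, 0.01), 2)), aggregate="auc")
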