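"""Domain containers and TSV readers/writers.

The pipeline starts from three plain-text inputs: a gene x library count
matrix, a sample sheet mapping libraries to ordered developmental stages
(days after anthesis, DAA) and replicates, and a many-to-many gene ->
category annotation map.  Everything downstream consumes the validated
containers defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "StudyDesign",
    "CategoryMap",
    "FrequencyMatrix",
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "read_design",
    "read_category_map",
    "stage_counts",
    "to_frequencies",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected TSV format."""


@dataclass
class CountMatrix:
    """Non-negative gene x library tag counts.

    ``integer`` records whether counts are raw integers (True) or weighted
    fractional values produced by category aggregation (False).
    """

    counts: pd.DataFrame  # genes x libraries
    integer: bool = True

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate library ids")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise FormatError("counts must be finite and non-negative")
        if self.integer and not np.allclose(values, np.round(values)):
            raise FormatError("integer matrix contains fractional values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def library_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class StudyDesign:
    """Ordered developmental stages with replicate structure.

    ``stages`` maps each stage time (DAA) to its library ids, ordered by
    increasing time.  ``intervals`` lists the consecutive stage pairs that
    are tested, with their duration in days.
    """

    stages: dict[float, list[str]]  # DAA -> library ids, insertion order = time order
    replicate_map: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = list(self.stages)
        if len(times) < 2:
            raise FormatError("need at least two stages")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise FormatError("stage times must be strictly increasing")
        if any(len(libs) < 1 for libs in self.stages.values()):
            raise FormatError("every stage needs at least one library")
        if not self.replicate_map:
            self.replicate_map = {
                lib: (t, i + 1)
                for t, libs in self.stages.items()
                for i, lib in enumerate(libs)
            }

    @property
    def stage_times(self) -> list[float]:
        return list(self.stages)

    @property
    def intervals(self) -> list[tuple[float, float, float]]:
        """Consecutive (from, to, duration-in-days) triples."""
        t = self.stage_times
        return [(a, b, b - a) for a, b in zip(t, t[1:])]

    @property
    def n_intervals(self) -> int:
        return len(self.stages) - 1

    def libraries(self, stage: float) -> list[str]:
        return self.stages[stage]


@dataclass
class CategoryMap:
    """Many-to-many gene -> category assignments.

    A gene may belong to 0..k categories; its multiplicity (the number of
    categories) is the divisor used by count-conserving aggregation.
    """

    assignments: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, cats in self.assignments.items():
            if any(not c for c in cats):
                raise FormatError(f"empty category id for gene {gene!r}")

    def multiplicity(self, gene: str) -> int:
        return len(self.assignments.get(gene, frozenset()))

    def categories(self, gene: str) -> frozenset[str]:
        return self.assignments.get(gene, frozenset())

    @property
    def all_categories(self) -> list[str]:
        return sorted({c for cats in self.assignments.values() for c in cats})


@dataclass
class FrequencyMatrix:
    """Relative expression frequencies p_ij (stage i, gene j).

    Each stage's frequencies sum to one; ``pbar`` is the per-gene mean
    frequency across the t stages, the baseline of the specificity measure.
    """

    p: pd.DataFrame  # stages x genes

    def __post_init__(self) -> None:
        sums = self.p.sum(axis=1).to_numpy()
        if np.any(self.p.to_numpy() < 0):
            raise FormatError("negative frequency")
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise FormatError("stage frequencies must sum to 1")

    @property
    def t(self) -> int:
        return self.p.shape[0]

    @property
    def pbar(self) -> pd.Series:
        return self.p.mean(axis=0)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def read_count_matrix(path, strict: bool = True) -> CountMatrix:
    """Read a gene x library count matrix from TSV.

    Header row holds library ids; the first column holds gene ids.  In
    strict mode duplicate gene ids are an error; otherwise duplicate rows
    are summed (the convention for contigs sharing an identifier).
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed TSV
        raise FormatError(f"cannot parse count matrix {path}: {exc}") from exc
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(f"non-numeric cell at row {row!r}, column {col!r}")
    neg = df.lt(0)
    if neg.any().any():
        row = df.index[neg.any(axis=1)][0]
        col = df.columns[neg.any(axis=0)][0]
        raise FormatError(f"negative count at row {row!r}, column {col!r}")
    if df.index.has_duplicates:
        if strict:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids (strict mode): {dupes[:5]}")
        df = df.groupby(level=0, sort=False).sum()
    integer = bool(np.allclose(df.to_numpy(), np.round(df.to_numpy())))
    return CountMatrix(counts=df, integer=integer)


def write_count_matrix(cm: CountMatrix, path) -> None:
    df = cm.counts
    if cm.integer:
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> StudyDesign:
    """Read a sample sheet (library_id, stage_daa, replicate) into a design.

    Stages are sorted by DAA regardless of file order.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"library_id", "stage_daa", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(f"sample sheet needs columns {sorted(required)}")
    if df["library_id"].duplicated().any():
        raise FormatError("duplicate library_id in sample sheet")
    daa = pd.to_numeric(df["stage_daa"], errors="coerce")
    if daa.isna().any():
        raise FormatError("non-numeric stage_daa")
    stages: dict[float, list[str]] = {}
    for t in sorted(daa.unique()):
        sub = df[daa == t].sort_values("replicate")
        stages[float(t)] = sub["library_id"].astype(str).tolist()
    replicate_map = {
        str(r.library_id): (float(r.stage_daa), int(r.replicate))
        for r in df.itertuples()
    }
    return StudyDesign(stages=stages, replicate_map=replicate_map)


def write_design(design: StudyDesign, path) -> None:
    rows = [
        {"library_id": lib, "stage_daa": t, "replicate": i + 1}
        for t, libs in design.stages.items()
        for i, lib in enumerate(libs)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_category_map(path) -> CategoryMap:
    """Read a headerless two-column (gene_id, category_id) TSV.

    Duplicate identical pairs collapse to one assignment.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["gene_id", "category_id"], dtype=str
    )
    if df["category_id"].isna().any() or (df["category_id"] == "").any():
        raise FormatError("empty category id")
    assignments: dict[str, set[str]] = {}
    for gene, cat in zip(df["gene_id"], df["category_id"]):
        assignments.setdefault(gene, set()).add(cat)
    return CategoryMap(assignments={g: frozenset(c) for g, c in assignments.items()})


def write_category_map(cmap: CategoryMap, path) -> None:
    rows = [
        {"gene_id": g, "category_id": c}
        for g, cats in cmap.assignments.items()
        for c in sorted(cats)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Stage-level aggregation
# ---------------------------------------------------------------------------


def stage_counts(cm: CountMatrix, design: StudyDesign) -> pd.DataFrame:
    """Sum replicate libraries per stage: genes x stages.

    Per-stage quantities (richness, frequencies, detection) are computed on
    the replicate-summed counts; statistical testing stays at the
    replicate level.
    """
    cols = {}
    for t, libs in design.stages.items():
        missing = [l for l in libs if l not in cm.counts.columns]
        if missing:
            raise FormatError(f"libraries {missing} not in count matrix")
        cols[t] = cm.counts[libs].sum(axis=1)
    return pd.DataFrame(cols)


def to_frequencies(cm: CountMatrix, design: StudyDesign) -> FrequencyMatrix:
    """Relative expression frequencies per stage (replicates summed first)."""
    sc = stage_counts(cm, design)
    totals = sc.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise FormatError(f"stage(s) with all-zero counts: {bad}")
    p = (sc / totals).T  # stages x genes
    return FrequencyMatrix(p=p)
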