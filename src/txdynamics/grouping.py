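"""Count-conserving weighted aggregation of genes into categories.

A gene annotated to k categories contributes count/k to each of them, so
the aggregated matrix has exactly the same column totals as the source
matrix — no statistical evidence is created or destroyed.  Genes with no
annotation are pooled into a reserved 'offset' row that is kept in the
matrix (it preserves library sizes and informs dispersion estimation) but
is never tested and never enters the pattern census.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CategoryMap, CountMatrix, StudyDesign
from .dge import interval_test
from .patterns import PatternTable, classify_patterns

__all__ = ["OFFSET_ID", "GroupMatrix", "build_group_matrix", "test_groups"]

OFFSET_ID = "__offset__"


@dataclass
class GroupMatrix:
    """Weighted category x library sums, with the untested offset row."""

    counts: pd.DataFrame  # categories (+ offset) x libraries, fractional
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def category_ids(self) -> list[str]:
        return [c for c in self.counts.index if c != OFFSET_ID]

    def n_genes(self, category: str) -> int:
        return len(self.provenance.get(category, []))


def build_group_matrix(cm: CountMatrix, cats: CategoryMap) -> GroupMatrix:
    """Aggregate gene counts into weighted category rows.

    Each annotated gene's counts are divided by its category multiplicity
    and added to every category it belongs to; unannotated genes sum into
    the offset row.  Column sums are conserved exactly.
    """
    genes = cm.gene_ids
    mult = np.array([cats.multiplicity(g) for g in genes], dtype=float)
    categories = cats.all_categories
    cat_index = {c: i for i, c in enumerate(categories)}
    # weight matrix would be sparse; accumulate row-wise instead
    out = np.zeros((len(categories) + 1, cm.shape[1]))
    counts = cm.counts.to_numpy(dtype=float)
    provenance: dict[str, list[str]] = {c: [] for c in categories}
    for gi, g in enumerate(genes):
        m = mult[gi]
        if m == 0:
            out[-1] += counts[gi]
            continue
        w = counts[gi] / m
        for c in cats.categories(g):
            out[cat_index[c]] += w
            provenance[c].append(g)
    df = pd.DataFrame(
        out, index=categories + [OFFSET_ID], columns=cm.library_ids
    )
    return GroupMatrix(counts=df, provenance=provenance)


def test_groups(
    gm: GroupMatrix,
    design: StudyDesign,
    fdr_level: float = 0.01,
    prior_df: float = 10.0,
    dispersion: str = "tagwise",
    drop_zero: bool = True,
) -> tuple[dict[tuple[float, float], pd.DataFrame], PatternTable]:
    """Run the exact-test workflow on category rows.

    Weighted sums are rounded half-to-even at the test boundary.  The
    offset row contributes to library sizes and dispersion estimation but
    is excluded from p/q computation and from the census.  Categories with
    zero total count are dropped from testing.
    """
    rounded = np.rint(gm.counts).astype(np.int64)
    lib_sizes = rounded.sum(axis=0)
    testable = np.array(
        [
            c != OFFSET_ID and (not drop_zero or rounded.loc[c].sum() > 0)
            for c in rounded.index
        ]
    )
    results: dict[tuple[float, float], pd.DataFrame] = {}
    state_cols = {}
    for t_a, t_b, _dur in design.intervals:
        res = interval_test(
            rounded,
            design.libraries(t_a),
            design.libraries(t_b),
            fdr_level=fdr_level,
            prior_df=prior_df,
            dispersion=dispersion,
            lib_sizes=lib_sizes,
            test_mask=testable,
        )
        results[(t_a, t_b)] = res[testable]
        state_cols[f"{t_a:g}-{t_b:g}"] = res.loc[testable, "state"]
    if not testable.any():
        k = design.n_intervals
        return results, PatternTable.from_census(np.zeros(3**k, dtype=int), k=k)
    states = pd.DataFrame(state_cols)
    return results, classify_patterns(states)
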