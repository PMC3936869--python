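"""Packaged reference pattern census.

A published 27-pattern census from a chili pepper (Capsicum annuum) fruit
development study — 34,066 genes, 875 Biological Process categories and
152 Metabolic Pathway categories sampled at 10, 20, 40 and 60 days after
anthesis — ships with the package so the census arithmetic (transition
probabilities, interval marginals, per-day rates, cross-census
correlations) is exercisable without any sequencing data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_census"]


def load_reference_census() -> pd.DataFrame:
    """Load the packaged census: columns id, pattern, genes, bp, mp."""
    ref = resources.files("txdynamics").joinpath("data/pattern_census_fruit.tsv")
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    expected_totals = {"genes": 34066, "bp": 875, "mp": 152}
    for col, tot in expected_totals.items():
        if int(df[col].sum()) != tot:
            raise RuntimeError(f"reference census corrupted: {col} sums to {df[col].sum()}")
    return df
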