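"""End-to-end pipeline: richness -> infostats -> DGE -> patterns -> grouping.

``run_pipeline`` ties the stages together from a :class:`PipelineConfig`
and writes table-shaped TSV reports plus a machine-readable JSON summary.
``census_summary`` is the census-only entry point: it reproduces all the
pattern-census arithmetic (transition probabilities, marginals, per-day
rates, changed-unit totals) directly from a 3^k-cell census, with no
sequencing data involved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    CountMatrix,
    StudyDesign,
    read_category_map,
    read_count_matrix,
    read_design,
    to_frequencies,
)
from .dge import test_all_intervals
from .grouping import build_group_matrix, test_groups
from .infotheory import info_stats
from .patterns import (
    PatternTable,
    changed_units,
    classify_patterns,
    detection_venn,
    exclusive_ubiquitous_ratio,
    interval_marginals,
    transition_matrix,
)
from .richness import richness_report

log = logging.getLogger("txdynamics")

__all__ = ["PipelineConfig", "run_pipeline", "census_summary"]


@dataclass
class PipelineConfig:
    counts: str | Path = ""
    design: str | Path = ""
    categories: str | Path | None = None
    out_dir: str | Path = "txdynamics_out"
    fdr_level: float = 0.01
    prior_df: float = 10.0
    dispersion: str = "tagwise"
    strict_ids: bool = True
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")


def census_summary(
    pt: PatternTable, design: StudyDesign
) -> dict:
    """All census arithmetic for one pattern table, as plain numbers."""
    marg = interval_marginals(pt, design)
    n_changed, n_changes = changed_units(pt)
    transitions = {}
    for pair in range(pt.k - 1):
        tm = transition_matrix(pt, pair)
        transitions[f"pair_{pair + 1}_to_{pair + 2}"] = {
            a: {b: (None if np.isnan(tm.loc[a, b]) else float(tm.loc[a, b]))
                for b in tm.columns}
            for a in tm.index
        }
    return {
        "n_units": pt.n_units,
        "census": pt.census.tolist(),
        "n_changed_units": n_changed,
        "n_total_changes": n_changes,
        "marginals": json.loads(marg.to_json(orient="index")),
        "transitions": transitions,
    }


def _run_stage(name: str, fn, *args, **kwargs):
    try:
        log.info("stage %s", name)
        return fn(*args, **kwargs)
    except Exception as exc:
        raise RuntimeError(f"[{name}] {exc}") from exc


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the JSON summary as a dict (also written to summary.json).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("txdynamics %s, fdr=%g, prior_df=%g, seed=%d",
             __version__, cfg.fdr_level, cfg.prior_df, cfg.seed)

    cm: CountMatrix = _run_stage(
        "read_counts", read_count_matrix, cfg.counts, cfg.strict_ids
    )
    design: StudyDesign = _run_stage("read_design", read_design, cfg.design)

    rich = _run_stage("richness", richness_report, cm, design)
    rich.to_csv(out / "richness.tsv", sep="\t")

    fm = _run_stage("frequencies", to_frequencies, cm, design)
    stats = _run_stage("infostats", info_stats, fm)
    stats.to_frame().to_csv(out / "infostats.tsv", sep="\t")
    stats.specificity.to_csv(out / "gene_specificity.tsv", sep="\t")

    results = _run_stage(
        "dge", test_all_intervals, cm, design,
        cfg.fdr_level, cfg.prior_df, cfg.dispersion,
    )
    states = pd.DataFrame(
        {f"{a:g}-{b:g}": res["state"] for (a, b), res in results.items()}
    )
    long = pd.concat(
        {f"{a:g}-{b:g}": res for (a, b), res in results.items()}, axis=1
    )
    long.to_csv(out / "dge.tsv", sep="\t")

    pt = _run_stage("patterns", classify_patterns, states)
    pt.to_frame().to_csv(out / "pattern_census.tsv", sep="\t", index=False)
    if pt.ids is not None:
        pt.ids.to_csv(out / "gene_patterns.tsv", sep="\t")
    summary: dict = {
        "version": __version__,
        "parameters": {
            "fdr_level": cfg.fdr_level,
            "prior_df": cfg.prior_df,
            "dispersion": cfg.dispersion,
            "seed": cfg.seed,
        },
        "genes": census_summary(pt, design),
    }

    venn = _run_stage("venn", detection_venn, cm, design)
    venn.to_csv(out / "venn.tsv", sep="\t", header=["n_genes"])
    summary["venn"] = {
        "cells": venn.to_dict(),
        "exclusive_ubiquitous_ratio": exclusive_ubiquitous_ratio(venn),
    }
    summary["richness"] = json.loads(rich.to_json(orient="index"))
    summary["infostats"] = json.loads(stats.to_frame().to_json(orient="index"))

    if cfg.categories:
        cmap = _run_stage("read_categories", read_category_map, cfg.categories)
        gm = _run_stage("group_matrix", build_group_matrix, cm, cmap)
        cat_results, cat_pt = _run_stage(
            "group_test", test_groups, gm, design,
            cfg.fdr_level, cfg.prior_df, cfg.dispersion,
        )
        cat_pt.to_frame().to_csv(
            out / "category_census.tsv", sep="\t", index=False
        )
        cat_long = pd.concat(
            {f"{a:g}-{b:g}": res for (a, b), res in cat_results.items()}, axis=1
        )
        cat_long.to_csv(out / "categories.tsv", sep="\t")
        summary["categories"] = census_summary(cat_pt, design)
    else:
        log.info("no category map given; grouping stage skipped")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
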