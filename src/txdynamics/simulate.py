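"""Synthetic count matrices with planted D/S/I expression patterns.

The generator emulates the data shape of a bulk RNA-seq developmental
time course: four stages (10, 20, 40, 60 DAA) with two biological
replicates each, about two million reads per stage, tens of thousands of
genes with NB-distributed counts over a heavy-tailed (log-normal)
abundance spectrum, a dominant all-steady fraction (~83% of genes) and
planted decrease/increase steps of a configurable log2 magnitude for the
rest.  It also draws redundant gene -> category maps so the aggregation
machinery is testable end to end.

Counts are NB(mean mu, dispersion phi) with variance mu + phi mu^2;
phi = 0 gives Poisson counts.  Pattern steps act multiplicatively on the
stage means in stage order (D multiplies by 2^-effect, I by 2^+effect),
and each stage's relative abundances are renormalized so library depth is
controlled; library depths are jittered +/-10% uniform around the target
to exercise the normalization machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import CategoryMap, CountMatrix, StudyDesign
from .patterns import id_to_states

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_counts",
    "simulate_category_map",
]


def steady_pattern_id(k: int = 3) -> int:
    """Id of the all-steady pattern (14 for k = 3)."""
    return sum(3**j for j in range(k)) + 1


def default_pattern_mixture(
    steady_mass: float | None = None, k: int = 3
) -> np.ndarray:
    """Default mixture over the 3^k patterns.

    With no argument (k = 3), the published gene-pattern census frequencies
    are used: ~83% steady and a non-steady distribution dominated by
    single-change patterns, as observed in the fruit-development study.
    With ``steady_mass`` given, that mass goes on the all-steady pattern
    and the remainder is spread uniformly (``steady_mass=1.0`` is the
    all-steady null).
    """
    n = 3**k
    if steady_mass is None:
        if k != 3:
            raise ValueError("census-based mixture is only defined for k=3")
        from .reference import load_reference_census

        census = load_reference_census()["genes"].to_numpy(dtype=float)
        return census / census.sum()
    mix = np.full(n, (1.0 - steady_mass) / max(n - 1, 1))
    mix[steady_pattern_id(k) - 1] = steady_mass
    return mix


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic time course.

    Defaults mirror the real study's shape: 4 stages x 2 replicates,
    2e6 reads per stage, ~83% steady genes, |log2 FC| = 2 per planted
    step.  ``dispersion`` is the NB phi (variance mu + phi mu^2);
    ``baseline_sigma`` is the log-normal sigma of per-gene baseline
    abundance (heavy tail, so rare genes exist and richness/coverage
    estimators have something to estimate).
    """

    n_genes: int = 20000
    stages: tuple[float, ...] = (10.0, 20.0, 40.0, 60.0)
    replicates: int = 2
    reads_per_stage: float = 2e6
    dispersion: float = 0.01
    pattern_mixture: np.ndarray = field(
        default_factory=lambda: default_pattern_mixture()
    )
    effect_size: float = 2.0
    baseline_sigma: float = 1.5
    depth_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.pattern_mixture = np.asarray(self.pattern_mixture, dtype=float)
        k = len(self.stages) - 1
        if self.pattern_mixture.shape != (3**k,):
            raise ValueError(f"pattern_mixture must have 3^{k} entries")
        if not np.isclose(self.pattern_mixture.sum(), 1.0):
            raise ValueError("pattern_mixture must sum to 1")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_genes < 1 or self.replicates < 1:
            raise ValueError("n_genes and replicates must be positive")


@dataclass
class SimulationTruth:
    """Planted pattern per gene and expected relative abundance per stage."""

    true_pattern: pd.Series  # gene -> pattern id 1..3^k
    true_mean: pd.DataFrame  # genes x stages, relative abundance (cols sum to 1)


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, StudyDesign, SimulationTruth]:
    """Draw a count matrix, its design, and the ground truth."""
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.stages) - 1
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]

    baseline = rng.lognormal(mean=0.0, sigma=cfg.baseline_sigma, size=cfg.n_genes)
    pattern_ids = (
        rng.choice(3**k, size=cfg.n_genes, p=cfg.pattern_mixture) + 1
    )

    # multiplicative steps per stage, cumulative in stage order
    step = {"D": 2.0**-cfg.effect_size, "S": 1.0, "I": 2.0**cfg.effect_size}
    mult = np.ones((cfg.n_genes, len(cfg.stages)))
    states = np.array(
        [id_to_states(pid, k) for pid in pattern_ids]
    )  # genes x k
    for j in range(k):
        factors = np.vectorize(step.__getitem__)(states[:, j])
        mult[:, j + 1] = mult[:, j] * factors

    abund = baseline[:, None] * mult
    rel = abund / abund.sum(axis=0, keepdims=True)  # per-stage relative abundance

    lib_cols = {}
    design_stages: dict[float, list[str]] = {}
    depth_target = cfg.reads_per_stage / cfg.replicates
    for si, t in enumerate(cfg.stages):
        design_stages[float(t)] = []
        for r in range(cfg.replicates):
            lib = f"d{t:g}_r{r + 1}"
            design_stages[float(t)].append(lib)
            depth = depth_target * rng.uniform(
                1 - cfg.depth_jitter, 1 + cfg.depth_jitter
            )
            mu = depth * rel[:, si]
            if cfg.dispersion == 0:
                counts = rng.poisson(mu)
            else:
                r_nb = 1.0 / cfg.dispersion
                counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
            lib_cols[lib] = counts
    cm = CountMatrix(
        counts=pd.DataFrame(lib_cols, index=genes), integer=True
    )
    design = StudyDesign(stages=design_stages)
    truth = SimulationTruth(
        true_pattern=pd.Series(pattern_ids, index=genes, name="pattern_id"),
        true_mean=pd.DataFrame(rel, index=genes, columns=list(cfg.stages)),
    )
    return cm, design, truth


def simulate_category_map(
    n_genes: int,
    n_categories: int,
    mean_multiplicity: float = 2.0,
    frac_unannotated: float = 0.2,
    seed: int = 0,
) -> CategoryMap:
    """Draw a redundant gene -> category map.

    Annotated genes receive a zero-truncated Poisson number of distinct
    categories (``mean_multiplicity`` is the rate of the underlying
    Poisson before truncation), drawn uniformly without replacement.
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if not 0 <= frac_unannotated < 1:
        raise ValueError("frac_unannotated must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    cats = [f"cat{j:04d}" for j in range(n_categories)]
    annotated = rng.random(n_genes) >= frac_unannotated
    mult = np.zeros(n_genes, dtype=int)
    todo = annotated.copy()
    while todo.any():  # rejection-sample the zero-truncated Poisson
        draw = rng.poisson(mean_multiplicity, size=int(todo.sum()))
        mult[np.flatnonzero(todo)] = draw
        todo[np.flatnonzero(todo)] = draw == 0
    mult = np.minimum(mult, n_categories)
    assignments = {}
    for gi in np.flatnonzero(annotated):
        chosen = rng.choice(n_categories, size=mult[gi], replace=False)
        assignments[genes[gi]] = frozenset(cats[j] for j in chosen)
    return CategoryMap(assignments=assignments)
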