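"""D/S/I expression-pattern classification and census arithmetic.

Each unit (gene or category) carries one state per consecutive interval:
significant Decrease (D), Steady (S, not significant at the chosen FDR) or
significant Increase (I).  With k intervals there are 3^k patterns; the
canonical id encodes the state triple in base 3 with D=0, S=1, I=2:

    id = 9*s1 + 3*s2 + s3 + 1   (k = 3)

so DDD=1, SSS=14, III=27 in lexicographic order with D < S < I.  The
27-cell census drives transition probabilities, per-interval marginals,
per-day change rates and cross-census correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .datamodel import CountMatrix, StudyDesign, stage_counts

__all__ = [
    "STATES",
    "PatternTable",
    "states_to_id",
    "id_to_states",
    "classify_patterns",
    "transition_matrix",
    "interval_marginals",
    "pattern_correlation",
    "changed_units",
    "detection_venn",
    "exclusive_ubiquitous_ratio",
]

STATES = ("D", "S", "I")
_STATE_CODE = {"D": 0, "S": 1, "I": 2}


def states_to_id(states) -> int:
    """Encode a state tuple, e.g. ('D','I','S') -> 8."""
    code = 0
    for s in states:
        code = 3 * code + _STATE_CODE[s]
    return code + 1


def id_to_states(pattern_id: int, k: int = 3) -> tuple[str, ...]:
    """Decode a pattern id into its state tuple."""
    code = pattern_id - 1
    if not 0 <= code < 3**k:
        raise ValueError(f"pattern id {pattern_id} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(STATES[code % 3])
        code //= 3
    return tuple(reversed(out))


def _slot_states(k: int) -> np.ndarray:
    """(3^k, k) array of state codes for all patterns in id order."""
    ids = np.arange(3**k)
    return np.stack(
        [(ids // 3 ** (k - 1 - j)) % 3 for j in range(k)], axis=1
    )


@dataclass
class PatternTable:
    """Per-unit pattern assignment plus the 3^k-cell census.

    ``states`` is units x intervals (may be empty when the table was built
    from a census alone, e.g. a published Table-2-style census).
    """

    census: np.ndarray  # length 3^k, id order
    k: int
    states: pd.DataFrame | None = None
    ids: pd.Series | None = None

    def __post_init__(self) -> None:
        self.census = np.asarray(self.census)
        if self.census.shape != (3**self.k,):
            raise ValueError(f"census must have 3^{self.k} cells")
        if np.any(self.census < 0):
            raise ValueError("negative census cell")

    @property
    def n_units(self) -> int:
        return int(self.census.sum())

    @classmethod
    def from_census(cls, census, k: int = 3) -> "PatternTable":
        return cls(census=np.asarray(census), k=k)

    def to_frame(self) -> pd.DataFrame:
        """Table-2-shaped census: id, pattern, count, percent."""
        ids = np.arange(1, 3**self.k + 1)
        pats = ["".join(id_to_states(i, self.k)) for i in ids]
        pct = 100.0 * self.census / max(self.n_units, 1)
        return pd.DataFrame(
            {"id": ids, "pattern": pats, "count": self.census, "percent": pct}
        )


def classify_patterns(interval_states: pd.DataFrame) -> PatternTable:
    """Classify units from per-interval D/S/I calls.

    ``interval_states`` is units x intervals with entries 'D'/'S'/'I'
    (columns in interval order).  Missing states are an error.
    """
    if interval_states.isna().any().any():
        raise ValueError("missing interval state")
    k = interval_states.shape[1]
    codes = interval_states.apply(lambda col: col.map(_STATE_CODE))
    if codes.isna().any().any():
        raise ValueError("states must be 'D', 'S' or 'I'")
    arr = codes.to_numpy(dtype=int)
    ids = arr @ (3 ** np.arange(k - 1, -1, -1)) + 1
    census = np.bincount(ids - 1, minlength=3**k)
    return PatternTable(
        census=census,
        k=k,
        states=interval_states,
        ids=pd.Series(ids, index=interval_states.index, name="pattern_id"),
    )


def transition_matrix(pt: PatternTable, pair: int) -> pd.DataFrame:
    """Conditional probabilities P(state at interval pair+1 | state at pair).

    ``pair`` indexes the earlier interval of the adjacent pair (0-based).
    Rows with zero support are NaN.  Row supports are attached in
    ``attrs['support']``.
    """
    if not 0 <= pair < pt.k - 1:
        raise ValueError(f"pair must be in [0, {pt.k - 2}]")
    slots = _slot_states(pt.k)
    joint = np.zeros((3, 3))
    for a in range(3):
        for b in range(3):
            mask = (slots[:, pair] == a) & (slots[:, pair + 1] == b)
            joint[a, b] = pt.census[mask].sum()
    support = joint.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = joint / support[:, None]
    out = pd.DataFrame(probs, index=list(STATES), columns=list(STATES))
    out.attrs["support"] = pd.Series(support, index=list(STATES))
    return out


def interval_marginals(pt: PatternTable, design: StudyDesign) -> pd.DataFrame:
    """Per-interval D/S/I counts, total changes, and changes per day.

    Also appends a 'Total' row summing counts over intervals.
    """
    intervals = design.intervals
    if len(intervals) != pt.k:
        raise ValueError("design intervals do not match pattern length")
    slots = _slot_states(pt.k)
    rows = []
    for j, (t_a, t_b, dur) in enumerate(intervals):
        n = [int(pt.census[slots[:, j] == s].sum()) for s in range(3)]
        changes = n[0] + n[2]
        rows.append(
            {
                "interval": f"{t_a:g}-{t_b:g}",
                "n_D": n[0],
                "n_S": n[1],
                "n_I": n[2],
                "changes": changes,
                "duration_days": dur,
                "changes_per_day": changes / dur,
            }
        )
    df = pd.DataFrame(rows).set_index("interval")
    total = df[["n_D", "n_S", "n_I", "changes"]].sum()
    total["duration_days"] = df["duration_days"].sum()
    total["changes_per_day"] = np.nan
    df.loc["Total"] = total
    return df


def pattern_correlation(census_a, census_b) -> float:
    """Pearson correlation between two pattern censuses (raw counts)."""
    a = np.asarray(census_a, dtype=float)
    b = np.asarray(census_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("censuses must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance census")
    return float(_stats.pearsonr(a, b).statistic)


def changed_units(pt: PatternTable) -> tuple[int, int]:
    """(units with >= 1 change, total changes summed over intervals).

    A unit changed iff its pattern is not the all-steady one; each non-S
    letter of a pattern counts as one change.
    """
    slots = _slot_states(pt.k)
    all_steady = int(np.flatnonzero((slots == 1).all(axis=1))[0])
    n_changed = pt.n_units - int(pt.census[all_steady])
    non_s = (slots != 1).sum(axis=1)
    n_total_changes = int((pt.census * non_s).sum())
    return n_changed, n_total_changes


def detection_venn(cm: CountMatrix, design: StudyDesign) -> pd.Series:
    """Partition detected genes by the set of stages where they appear.

    A gene is detected at a stage when its replicate-summed count is
    >= 1 read.  Returns counts for all 2^t - 1 non-empty stage subsets,
    keyed by '+'-joined stage times; genes detected nowhere are excluded.
    """
    sc = stage_counts(cm, design)
    detected = sc.to_numpy() >= 1
    t = detected.shape[1]
    stages = [f"{s:g}" for s in sc.columns]
    keys = []
    for mask in range(1, 2**t):
        keys.append("+".join(stages[i] for i in range(t) if mask & (1 << i)))
    cells = pd.Series(0, index=keys, dtype=int)
    gene_mask = detected @ (1 << np.arange(t))
    counts = np.bincount(gene_mask, minlength=2**t)
    for mask in range(1, 2**t):
        cells.iloc[mask - 1] = int(counts[mask])
    return cells


def exclusive_ubiquitous_ratio(cells: pd.Series) -> float:
    """Ratio of single-stage-exclusive genes to genes detected at every stage.

    ``cells`` is a Venn partition keyed by '+'-joined stage labels, as
    returned by :func:`detection_venn`.
    """
    n_stages = max(k.count("+") for k in cells.index) + 1
    singles = sum(v for k, v in cells.items() if k.count("+") == 0)
    full = [v for k, v in cells.items() if k.count("+") == n_stages - 1]
    if not full or full[0] == 0:
        raise ValueError("no genes detected at every stage")
    return singles / full[0]
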