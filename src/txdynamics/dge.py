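"""Exact negative-binomial test between two replicate groups.

The classic count-based differential-expression workflow: libraries are
adjusted to a common size by NB quantile matching, a common dispersion is
estimated by conditional maximum likelihood, per-gene (tagwise) dispersions
are shrunk toward the common likelihood, and an exact conditional test is
run on the group sums.  P-values are converted to q-values with the Storey
procedure, and each gene is called Decreased / Steady / Increased per
interval at the chosen FDR level.

The NB is parameterized by mean mu and dispersion phi, variance
mu + phi * mu^2 (phi = 0 is Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from scipy.special import gammaln

from .datamodel import CountMatrix, StudyDesign

__all__ = [
    "DispersionEstimates",
    "equalize_libraries",
    "estimate_common_dispersion",
    "estimate_tagwise_dispersion",
    "exact_nb_test",
    "exact_nb_test_many",
    "qvalues",
    "interval_test",
    "test_all_intervals",
]

PHI_MIN = 1e-6
PHI_MAX = 10.0
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class DispersionEstimates:
    """Common and per-gene NB dispersions on the pseudo-count scale."""

    phi_common: float
    phi_tagwise: np.ndarray
    pseudo_lib_size: float
    prior_df: float


# ---------------------------------------------------------------------------
# Library-size equalization (NB quantile matching)
# ---------------------------------------------------------------------------


def equalize_libraries(
    counts: np.ndarray,
    lib_sizes: np.ndarray | None = None,
    phi: float = 0.0,
    groups: list[list[int]] | None = None,
) -> tuple[np.ndarray, float]:
    """Adjust every library to the geometric mean of the library sizes.

    Each count y in library j is mapped through the quantile of its fitted
    NB (mean = gene proportion x N_j, dispersion phi), approximated by the
    moment-matched gamma, onto the same quantile at the common library
    size.  When ``groups`` (lists of column indices) is given, the gene
    proportion is estimated within each group, so genes whose abundance
    differs between the tested groups are not distorted by a pooled mean.
    Equal library sizes leave the counts unchanged; zeros stay zero.

    Returns (pseudo_counts, common_lib_size).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be genes x libraries")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise ValueError("zero or negative library sum")
    common = float(np.exp(np.mean(np.log(lib_sizes))))
    if np.allclose(lib_sizes, common):
        return counts.copy(), common
    if groups is None:
        groups = [list(range(counts.shape[1]))]
    props = np.empty_like(counts)
    for cols in groups:
        p = counts[:, cols].sum(axis=1) / lib_sizes[cols].sum()
        props[:, cols] = p[:, None]
    mu_in = props * lib_sizes[None, :]
    mu_out = props * common
    pseudo = np.zeros_like(counts)
    pos = (mu_in > 0) & (counts > 0)
    # gamma with matching mean and variance: shape mu^2/v, scale v/mu
    scale_in = 1.0 + phi * mu_in[pos]
    shape_in = mu_in[pos] / scale_in
    scale_out = 1.0 + phi * mu_out[pos]
    shape_out = mu_out[pos] / scale_out
    # map through the survival function for accuracy in the upper tail
    logsf = stats.gamma.logsf(counts[pos], shape_in, scale=scale_in)
    pseudo[pos] = stats.gamma.isf(np.exp(logsf), shape_out, scale=scale_out)
    pseudo[~np.isfinite(pseudo)] = 0.0
    return pseudo, common


# ---------------------------------------------------------------------------
# Conditional NB log-likelihood in the dispersion
# ---------------------------------------------------------------------------


def _cond_loglik(group_counts: list[np.ndarray], phi: np.ndarray) -> np.ndarray:
    """Per-gene conditional NB log-likelihood at dispersion(s) ``phi``.

    Conditioning each gene on its within-group totals removes the mean
    parameter; only dispersion-dependent terms are kept.  ``phi`` may be a
    scalar or a per-gene vector.  Counts may be fractional (pseudo-counts);
    the gamma-function form extends the likelihood continuously.
    """
    phi = np.asarray(phi, dtype=float)
    r = 1.0 / np.maximum(phi, PHI_MIN / 10)
    ll = 0.0
    for y in group_counts:
        y = np.asarray(y, dtype=float)
        m = y.shape[1]
        z = y.sum(axis=1)
        rr = np.broadcast_to(np.atleast_1d(r), z.shape)
        ll = ll + (
            gammaln(y + rr[:, None]).sum(axis=1)
            - m * gammaln(rr)
            + gammaln(m * rr)
            - gammaln(z + m * rr)
        )
    return ll


def _golden_max(f, lo: np.ndarray, hi: np.ndarray, iters: int = 45):
    """Vectorized golden-section maximization of f over [lo, hi]."""
    lo = np.array(lo, dtype=float, copy=True)
    hi = np.array(hi, dtype=float, copy=True)
    for _ in range(iters):
        x1 = hi - _GOLDEN * (hi - lo)
        x2 = lo + _GOLDEN * (hi - lo)
        keep_upper = f(x1) < f(x2)  # maximum lies in [x1, hi]
        lo = np.where(keep_upper, x1, lo)
        hi = np.where(keep_upper, hi, x2)
    return (lo + hi) / 2.0


def estimate_common_dispersion(
    group_counts: list[np.ndarray],
    bounds: tuple[float, float] = (PHI_MIN, PHI_MAX),
) -> float:
    """Common dispersion maximizing the summed conditional log-likelihood.

    Grid search on a log scale refined by golden-section within the
    bracketing grid cells.
    """
    n_lib = sum(y.shape[1] for y in group_counts)
    if n_lib < 2:
        raise ValueError("need at least 2 libraries to estimate dispersion")
    # genes with all-zero totals contribute a constant; drop them
    keep = np.zeros(group_counts[0].shape[0], dtype=bool)
    for y in group_counts:
        keep |= np.asarray(y).sum(axis=1) > 0
    gc = [np.asarray(y, dtype=float)[keep] for y in group_counts]
    if not keep.any():
        return bounds[0]

    def total(phi_scalar: float) -> float:
        return float(_cond_loglik(gc, phi_scalar).sum())

    grid = np.geomspace(bounds[0], bounds[1], 41)
    vals = np.array([total(p) for p in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]

    def f(x):
        return np.array([total(float(v)) for v in np.atleast_1d(x)])

    phi = _golden_max(f, np.array([lo]), np.array([hi]))
    return float(np.clip(phi[0], bounds[0], bounds[1]))


def estimate_tagwise_dispersion(
    group_counts: list[np.ndarray],
    phi_common: float,
    prior_df: float = 10.0,
    bounds: tuple[float, float] = (PHI_MIN, PHI_MAX),
) -> np.ndarray:
    """Per-gene dispersions shrunk toward the common likelihood.

    Each gene maximizes its own conditional log-likelihood plus
    ``prior_df`` times the mean conditional log-likelihood over all genes
    (evaluated through a dense interpolant anchored at the common
    dispersion).  prior_df -> infinity recovers phi_common for every gene;
    prior_df = 0 is the per-gene conditional MLE.
    """
    gc = [np.asarray(y, dtype=float) for y in group_counts]
    n_genes = gc[0].shape[0]
    if n_genes == 0:
        return np.empty(0)

    # dense knots for the shared (mean) likelihood curve, anchored at phi_common
    coarse = np.geomspace(bounds[0], bounds[1], 60)
    fine = np.linspace(phi_common / 2, min(2 * phi_common, bounds[1]), 200)
    knots = np.unique(np.concatenate([coarse, fine, [phi_common]]))
    L = np.stack([_cond_loglik(gc, p) for p in knots], axis=1)  # genes x knots
    mean_ll = CubicSpline(knots, L.mean(axis=0))

    def objective(phi_vec: np.ndarray) -> np.ndarray:
        return _cond_loglik(gc, phi_vec) + prior_df * mean_ll(phi_vec)

    grid_obj = L + prior_df * mean_ll(knots)[None, :]
    i = np.argmax(grid_obj, axis=1)
    lo = knots[np.maximum(i - 1, 0)]
    hi = knots[np.minimum(i + 1, len(knots) - 1)]
    phi = _golden_max(objective, lo, hi)
    return np.clip(phi, bounds[0], bounds[1])


# ---------------------------------------------------------------------------
# Exact conditional test
# ---------------------------------------------------------------------------


def exact_nb_test(yA, yB, phi: float) -> float:
    """Two-sided exact test for a single gene.

    Conditional on the grand total, with equalized library sizes, the
    group-A sum follows the convolution of the group NB laws (negative
    hypergeometric; binomial in the Poisson limit phi = 0).  The p-value
    doubles the smaller tail, including the observed outcome, capped at 1.
    """
    yA = np.atleast_1d(np.asarray(yA, dtype=float))
    yB = np.atleast_1d(np.asarray(yB, dtype=float))
    p = exact_nb_test_many(
        yA.reshape(1, -1), yB.reshape(1, -1), np.array([float(phi)])
    )
    return float(p[0])


def exact_nb_test_many(
    yA: np.ndarray, yB: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Vectorized exact test over genes (rows of yA / yB).

    Group sums are rounded half-to-even to the integer lattice on which
    the conditional law lives.  Genes with zero grand total get p = 1.
    """
    yA = np.asarray(yA, dtype=float)
    yB = np.asarray(yB, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (yA.shape[0],))
    mA, mB = yA.shape[1], yB.shape[1]
    a = np.rint(yA.sum(axis=1)).astype(np.int64)
    b = np.rint(yB.sum(axis=1)).astype(np.int64)
    n = a + b
    pvals = np.ones(yA.shape[0])
    active = n > 0
    if not active.any():
        return pvals

    idx = np.flatnonzero(active)
    n_act = n[idx]
    a_act = a[idx]
    phi_act = phi[idx]

    # flat concatenation of the supports 0..n_g
    lens = n_act + 1
    offsets = np.concatenate([[0], np.cumsum(lens)])
    total_len = int(offsets[-1])
    seg = np.repeat(np.arange(len(idx)), lens)
    k = np.arange(total_len) - offsets[seg]
    n_flat = n_act[seg]
    phi_flat = phi_act[seg]

    logw = np.empty(total_len)
    pois = phi_flat == 0.0
    if pois.any():
        # Poisson limit: Binomial(n, mA / (mA + mB))
        pA = mA / (mA + mB)
        kk, nn = k[pois], n_flat[pois]
        logw[pois] = (
            gammaln(nn + 1)
            - gammaln(kk + 1)
            - gammaln(nn - kk + 1)
            + kk * np.log(pA)
            + (nn - kk) * np.log1p(-pA)
        )
    nb = ~pois
    if nb.any():
        rA = mA / phi_flat[nb]
        rB = mB / phi_flat[nb]
        kk, nn = k[nb], n_flat[nb]
        logw[nb] = (
            gammaln(kk + rA)
            - gammaln(kk + 1)
            - gammaln(rA)
            + gammaln(nn - kk + rB)
            - gammaln(nn - kk + 1)
            - gammaln(rB)
        )

    # per-segment normalization and tails
    seg_max = np.maximum.reduceat(logw, offsets[:-1])
    w = np.exp(logw - seg_max[seg])
    cw = np.concatenate([[0.0], np.cumsum(w)])
    tot = cw[offsets[1:]] - cw[offsets[:-1]]
    lower = cw[offsets[:-1] + a_act + 1] - cw[offsets[:-1]]
    upper = cw[offsets[1:]] - cw[offsets[:-1] + a_act]
    p = 2.0 * np.minimum(lower, upper) / tot
    pvals[idx] = np.minimum(p, 1.0)
    return pvals


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------


def qvalues(
    p_values,
    fdr_level: float = 0.01,
    pi0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Storey q-values and significance calls at ``fdr_level``.

    pi0 is estimated on the grid lambda = 0.05, ..., 0.95, smoothed with a
    cubic fit and evaluated at lambda = 0.95, clipped to (0, 1]; pass
    ``pi0`` to override the estimate.  Returns (q, significant).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
        coef = np.polyfit(lam, pi0_lam, 3)
        est = float(np.polyval(coef, lam[-1]))
        pi0 = float(np.clip(est, 1.0 / m, 1.0))
    else:
        pi0 = float(pi0)
        if not 0 < pi0 <= 1:
            raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, q <= fdr_level


# ---------------------------------------------------------------------------
# Interval workflow
# ---------------------------------------------------------------------------


def _interval_pvalues(
    counts: pd.DataFrame,
    libs_a: list[str],
    libs_b: list[str],
    lib_sizes: pd.Series | None,
    prior_df: float,
    dispersion: str,
) -> tuple[np.ndarray, np.ndarray, DispersionEstimates]:
    """Exact-test p-values and log2 fold changes for one stage pair."""
    raw = counts[libs_a + libs_b].to_numpy(dtype=float)
    if lib_sizes is None:
        sizes = raw.sum(axis=0)
    else:
        sizes = lib_sizes[libs_a + libs_b].to_numpy(dtype=float)
    # alternate equalization and estimation until the dispersion settles
    nA = len(libs_a)
    grp = [list(range(nA)), list(range(nA, raw.shape[1]))]
    phi_c = 0.01
    for _ in range(3):
        pseudo, common = equalize_libraries(raw, sizes, phi=phi_c, groups=grp)
        gc = [pseudo[:, :nA], pseudo[:, nA:]]
        phi_c = estimate_common_dispersion(gc)
    pseudo, common = equalize_libraries(raw, sizes, phi=phi_c, groups=grp)
    gc = [pseudo[:, :nA], pseudo[:, nA:]]
    if dispersion == "common":
        phi_g = np.full(raw.shape[0], phi_c)
    elif dispersion == "tagwise":
        phi_g = estimate_tagwise_dispersion(gc, phi_c, prior_df=prior_df)
    else:
        raise ValueError("dispersion must be 'common' or 'tagwise'")
    p = exact_nb_test_many(gc[0], gc[1], phi_g)
    prior = 0.125
    mean_a = gc[0].mean(axis=1) + prior
    mean_b = gc[1].mean(axis=1) + prior
    log2fc = np.log2(mean_b / mean_a)
    disp = DispersionEstimates(
        phi_common=phi_c,
        phi_tagwise=phi_g,
        pseudo_lib_size=common,
        prior_df=prior_df,
    )
    return p, log2fc, disp


def interval_test(
    counts: pd.DataFrame,
    libs_a: list[str],
    libs_b: list[str],
    fdr_level: float = 0.01,
    prior_df: float = 10.0,
    dispersion: str = "tagwise",
    lib_sizes: pd.Series | None = None,
    test_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full exact-test workflow for one consecutive stage pair.

    ``test_mask`` restricts the q-value computation and the D/S/I calls to
    a subset of rows (rows outside it still contribute to library sizes
    and dispersion estimation; they get q = NaN and state 'S').

    Returns a frame indexed like ``counts`` with columns
    p_value, q_value, log2_fold_change, state.
    """
    p, log2fc, disp = _interval_pvalues(
        counts, libs_a, libs_b, lib_sizes, prior_df, dispersion
    )
    if test_mask is None:
        test_mask = np.ones(len(p), dtype=bool)
    q = np.full(len(p), np.nan)
    sig = np.zeros(len(p), dtype=bool)
    if test_mask.any():
        q[test_mask], sig[test_mask] = qvalues(
            p[test_mask], fdr_level=fdr_level
        )
    state = np.where(sig & (log2fc > 0), "I", np.where(sig & (log2fc < 0), "D", "S"))
    out = pd.DataFrame(
        {
            "p_value": p,
            "q_value": q,
            "log2_fold_change": log2fc,
            "state": state,
        },
        index=counts.index,
    )
    out.attrs["dispersion"] = disp
    return out


def test_all_intervals(
    cm: CountMatrix,
    design: StudyDesign,
    fdr_level: float = 0.01,
    prior_df: float = 10.0,
    dispersion: str = "tagwise",
) -> dict[tuple[float, float], pd.DataFrame]:
    """Run the exact-test workflow on every consecutive stage pair.

    The q-value procedure is applied separately per interval.  Fractional
    (weighted) matrices are rounded half-to-even at the test boundary.
    """
    counts = cm.counts
    if not cm.integer:
        counts = np.rint(counts).astype(np.int64)
    results = {}
    for t_a, t_b, _dur in design.intervals:
        results[(t_a, t_b)] = interval_test(
            counts,
            design.libraries(t_a),
            design.libraries(t_b),
            fdr_level=fdr_level,
            prior_df=prior_df,
            dispersion=dispersion,
        )
    return results
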