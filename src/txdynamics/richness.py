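"""Expressed-gene richness and scaled mRNA-pool size per stage.

Sequencing depth bounds how many expressed genes a library can detect;
rare transcripts are missed exactly as rare species are missed in an
ecological survey.  From the per-stage detection spectrum (singletons f1,
doubletons f2) this module estimates:

* the Chao richness S_chao = S_obs + f1^2 / (2 f2) (bias-corrected
  S_obs + f1 (f1 - 1) / 2 when f2 = 0), a lower-bound estimate of the true
  number of expressed genes;
* Good's sample coverage C_hat = 1 - f1 / N, the estimated probability
  mass of the detected genes, and the scaled mRNA-pool size
  M_hat = N / C_hat.

Counts are summed over a stage's replicates before classifying genes as
detected/singleton/doubleton.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import CountMatrix, StudyDesign, stage_counts

__all__ = [
    "detection_counts",
    "chao_estimate",
    "good_coverage_and_M",
    "richness_report",
]


def detection_counts(cm: CountMatrix, design: StudyDesign) -> pd.DataFrame:
    """Per-stage totals and detection spectrum.

    Returns a frame indexed by stage DAA with columns N (total reads),
    S_obs (genes with >= 1 read), f1 (exactly 1), f2 (exactly 2).
    """
    sc = stage_counts(cm, design)
    rows = {}
    for t in sc.columns:
        col = sc[t].to_numpy()
        rows[t] = {
            "N": int(col.sum()),
            "S_obs": int((col >= 1).sum()),
            "f1": int((col == 1).sum()),
            "f2": int((col == 2).sum()),
        }
    return pd.DataFrame(rows).T[["N", "S_obs", "f1", "f2"]]


def chao_estimate(S_obs: int, f1: int, f2: int) -> float:
    """Chao estimate of true richness from singletons and doubletons."""
    if min(S_obs, f1, f2) < 0:
        raise ValueError("inputs must be non-negative")
    if f2 > 0:
        return S_obs + f1**2 / (2.0 * f2)
    return S_obs + f1 * (f1 - 1) / 2.0


def good_coverage_and_M(N: int, f1: int) -> tuple[float, float]:
    """Good's sample coverage C_hat = 1 - f1/N and M_hat = N / C_hat."""
    if N <= 0:
        raise ValueError("N must be positive")
    if not 0 <= f1 <= N:
        raise ValueError("f1 must lie in [0, N]")
    C_hat = 1.0 - f1 / N
    if C_hat <= 0:
        raise ValueError("coverage is zero (every read is a singleton)")
    return C_hat, N / C_hat


def richness_report(cm: CountMatrix, design: StudyDesign) -> pd.DataFrame:
    """Per-stage richness table with mean and standard-deviation rows.

    Columns: reads, genes_in_sample, f1, f2, chao, coverage, M_hat;
    rows: one per stage DAA plus 'Mean' and 'S' (sample sd).
    """
    det = detection_counts(cm, design)
    rows = []
    for t, r in det.iterrows():
        chao = chao_estimate(int(r.S_obs), int(r.f1), int(r.f2))
        if r.N > 0:
            C_hat, M_hat = good_coverage_and_M(int(r.N), int(r.f1))
        else:
            C_hat, M_hat = np.nan, np.nan
        rows.append(
            {
                "stage_daa": t,
                "reads": int(r.N),
                "genes_in_sample": int(r.S_obs),
                "f1": int(r.f1),
                "f2": int(r.f2),
                "chao": chao,
                "coverage": C_hat,
                "M_hat": M_hat,
            }
        )
    df = pd.DataFrame(rows).set_index("stage_daa")
    summary = pd.DataFrame(
        {c: [df[c].mean(), df[c].std(ddof=1)] for c in df.columns},
        index=["Mean", "S"],
    )
    return pd.concat([df, summary])
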