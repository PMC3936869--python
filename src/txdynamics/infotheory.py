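"""Transcriptome diversity, gene specificity and stage specialization.

Given the relative expression frequencies p_ij of gene j at stage i
(columns of a :class:`~txdynamics.datamodel.FrequencyMatrix`), this module
computes:

* diversity H_i = -sum_j p_ij log2 p_ij, the Shannon entropy of a stage's
  transcriptome in bits;
* the effective gene number G_i = 2^H_i, the count of equally expressed
  genes that would yield the same entropy;
* gene specificity S_j = (1/t) sum_i (p_ij / pbar_j) log2(p_ij / pbar_j),
  a Jensen-Shannon-style divergence of the gene's expression profile from
  the average transcriptome: 0 for a uniformly expressed gene, log2 t for
  a single-stage-exclusive one;
* stage specialization delta_i = sum_j p_ij S_j, the expression-weighted
  average specificity of the genes a stage expresses.

All logarithms are base 2; 0 * log 0 is taken as 0 throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import FrequencyMatrix

__all__ = [
    "InfoStats",
    "diversity",
    "effective_genes",
    "gene_specificity",
    "specialization",
    "info_stats",
]


@dataclass
class InfoStats:
    """Per-stage diversity/effective-genes/specialization + per-gene specificity."""

    H: pd.Series
    G: pd.Series
    delta: pd.Series
    specificity: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"H": self.H, "G": self.G, "delta": self.delta})
        gmax = df["G"].max()
        df["G_percent_of_max"] = 100.0 * df["G"] / gmax
        return df


def _xlog2x(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * np.log2(x[pos])
    return out


def diversity(fm: FrequencyMatrix) -> pd.Series:
    """Shannon entropy of each stage's frequencies, in bits."""
    p = fm.p.to_numpy(dtype=float)
    H = -_xlog2x(p).sum(axis=1)
    return pd.Series(H, index=fm.p.index, name="H")


def effective_genes(H) -> pd.Series | float:
    """Effective gene number G = 2^H."""
    if np.isscalar(H):
        return float(2.0**H)
    return (2.0 ** pd.Series(H)).rename("G")


def gene_specificity(fm: FrequencyMatrix) -> pd.Series:
    """Per-gene specificity in [0, log2 t].

    Genes undetected in every stage have undefined specificity; they are
    excluded (NaN) with a warning.
    """
    p = fm.p.to_numpy(dtype=float)
    t = fm.t
    pbar = p.mean(axis=0)
    S = np.full(p.shape[1], np.nan)
    pos = pbar > 0
    ratio = p[:, pos] / pbar[pos]
    S[pos] = _xlog2x(ratio).sum(axis=0) / t
    if (~pos).any():
        warnings.warn(
            f"{(~pos).sum()} gene(s) with all-zero frequencies excluded "
            "from specificity",
            stacklevel=2,
        )
    # clip tiny negative rounding residue at the uniform-profile boundary
    S[pos] = np.clip(S[pos], 0.0, np.log2(t))
    return pd.Series(S, index=fm.p.columns, name="specificity")


def specialization(fm: FrequencyMatrix, S: pd.Series) -> pd.Series:
    """Stage specialization: expression-weighted mean gene specificity."""
    Sv = S.reindex(fm.p.columns).to_numpy(dtype=float)
    p = fm.p.to_numpy(dtype=float)
    Sv = np.where(np.isnan(Sv), 0.0, Sv)  # all-zero genes carry no weight
    delta = p @ Sv
    return pd.Series(delta, index=fm.p.index, name="delta")


def info_stats(fm: FrequencyMatrix) -> InfoStats:
    """Compute all information-theoretic statistics for one frequency matrix."""
    H = diversity(fm)
    S = gene_specificity(fm)
    return InfoStats(
        H=H,
        G=effective_genes(H),
        delta=specialization(fm, S),
        specificity=S,
    )
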