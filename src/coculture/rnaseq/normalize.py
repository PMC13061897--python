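"""Count normalization: median-of-ratios size factors and TPM."""

from __future__ import annotations

import numpy as np
import pandas as pd


class SizeFactorError(ValueError):
    """No gene is nonzero in every sample; use a pseudo-reference instead."""


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    s_j = median over genes (with positive geometric mean across samples) of
    K[i,j] / geomean_i. All-zero genes are dropped first. With
    ``pseudo_reference=True`` the geometric mean is computed over nonzero
    entries only (fallback when no gene is observed in every sample).
    """
    K = counts.loc[(counts != 0).any(axis=1)].to_numpy(dtype=float)
    if K.size == 0:
        raise SizeFactorError("count matrix has no nonzero gene")
    with np.errstate(divide="ignore"):
        logK = np.log(K)
    all_pos = np.isfinite(logK).all(axis=1)
    if not pseudo_reference:
        if not all_pos.any():
            raise SizeFactorError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True"
            )
        ref = np.exp(logK[all_pos].mean(axis=1))
        ratios = K[all_pos] / ref[:, None]
        s = np.nanmedian(np.where(K[all_pos] > 0, ratios, np.nan), axis=0)
    else:
        ref = np.exp(np.nanmean(np.where(np.isfinite(logK), logK, np.nan), axis=1))
        ratios = np.where(K > 0, K / ref[:, None], np.nan)
        s = np.nanmedian(ratios, axis=0)
    if not np.all(np.isfinite(s)) or np.any(s <= 0):
        raise SizeFactorError("could not compute positive size factors for all samples")
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts / factors


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million. Columns sum to 1e6 (all-zero columns stay zero)."""
    L = lengths.reindex(counts.index)
    if L.isna().any():
        raise ValueError("every gene needs a length")
    if (L <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.div(L, axis=0)
    denom = rate.sum(axis=0)
    out = rate.div(denom.replace(0, np.nan), axis=1) * 1e6
    return out.fillna(0.0)
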