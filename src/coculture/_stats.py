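"""Shared statistical helpers used across modules."""

from __future__ import annotations

import numpy as np


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are ignored (returned as NaN) and do not count toward the
    number of tests.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def welch_ttest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test; returns (t, p)."""
    from scipy import stats

    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)
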