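"""Plate-reader well-scan aggregation and dose-response summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps


def wellscan_summary(grid: np.ndarray, stat: str = "mean",
                     shape: tuple[int, int] = (30, 30)) -> float:
    """Collapse one well's OD scan grid to a scalar."""
    g = np.asarray(grid, dtype=float)
    if g.shape != shape:
        raise ValueError(f"expected grid of shape {shape}, got {g.shape}")
    if stat == "mean":
        return float(g.mean())
    if stat == "median":
        return float(np.median(g))
    if stat == "integrated":
        return float(g.sum())
    raise ValueError(f"unknown stat {stat!r}")


def dose_table(
    wells: dict[str, np.ndarray],
    concentrations: dict[str, float],
    stat: str = "mean",
    shape: tuple[int, int] = (30, 30),
    fit: bool = True,
) -> tuple[pd.DataFrame, dict | None]:
    """Join well summaries to declared concentrations.

    Returns a per-concentration table (mean +/- SD over replicate wells)
    and, when ``fit``, a linear response-vs-concentration fit with slope,
    intercept and R^2.
    """
    missing = set(wells) - set(concentrations)
    if missing:
        raise ValueError(f"wells without declared concentration: {sorted(missing)}")
    rows = [
        {"well": w, "concentration": concentrations[w],
         "response": wellscan_summary(g, stat, shape)}
        for w, g in wells.items()
    ]
    per_well = pd.DataFrame(rows)
    table = (
        per_well.groupby("concentration")["response"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .sort_values("concentration", ignore_index=True)
    )
    fit_out = None
    if fit and per_well["concentration"].nunique() >= 2:
        res = sps.linregress(per_well["concentration"], per_well["response"])
        fit_out = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
            "p": float(res.pvalue),
            "stderr": float(res.stderr),
        }
    return table, fit_out
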