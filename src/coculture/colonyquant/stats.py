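"""Condition comparisons of colony areas: pairwise t-tests and Tukey HSD."""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .._stats import bh_adjust


@dataclass
class AreaComparison:
    method: str
    table: pd.DataFrame  # condition_a, condition_b, stat, p, padj

    def significant_pairs(self, alpha: float = 0.05) -> set[frozenset]:
        sig = self.table[self.table["padj"] < alpha]
        return {frozenset((a, b)) for a, b in zip(sig["condition_a"], sig["condition_b"])}


def compare_areas(
    areas_by_condition: dict[str, np.ndarray | list],
    method: str = "ttest_bh",
) -> AreaComparison:
    """All pairwise comparisons of colony areas between conditions.

    ``ttest_bh``: Welch two-sample t-tests with BH adjustment across the
    pair family. ``tukey``: Tukey's HSD on the one-way layout (adjusted p
    from the studentized range). Conditions with a single replicate are
    excluded with a warning.
    """
    groups = {}
    for cond, vals in areas_by_condition.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            warnings.warn(f"condition {cond!r} has < 2 replicates; excluded")
            continue
        groups[cond] = v
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions with >= 2 replicates")
    conds = sorted(groups)

    if method == "ttest_bh":
        rows = []
        for a, b in itertools.combinations(conds, 2):
            t, p = sps.ttest_ind(groups[a], groups[b], equal_var=False)
            rows.append({"condition_a": a, "condition_b": b,
                         "stat": float(t), "p": float(p)})
        tab = pd.DataFrame(rows)
        tab["padj"] = bh_adjust(tab["p"].to_numpy())
        return AreaComparison("ttest_bh", tab)

    if method == "tukey":
        res = sps.tukey_hsd(*(groups[c] for c in conds))
        rows = []
        for i, j in itertools.combinations(range(len(conds)), 2):
            rows.append(
                {
                    "condition_a": conds[i],
                    "condition_b": conds[j],
                    "stat": float(res.statistic[i, j]),
                    "p": float(res.pvalue[i, j]),
                    "padj": float(res.pvalue[i, j]),  # Tukey p is already adjusted
                }
            )
        return AreaComparison("tukey", pd.DataFrame(rows))

    raise ValueError(f"unknown method {method!r}")
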