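"""Dual-contrast attribution of metabolite features to producer strains.

To decide whether focal strain X produces a feature in response to partner
Y, the X-Y samples are compared against X-X (self pairing) and against Y-X
(the partner's mirror sample). A feature is attributed iff each contrast
shows, on at least one day, a BH-adjusted p <= alpha together with a log2
fold increase >= lfc_min. A symmetric (diffusible) feature elevated in both
X-Y and Y-X fails the mirror contrast by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .._stats import bh_adjust
from .peaktable import PeakTable

CONTRASTS = ("XY_vs_XX", "XY_vs_YX")


@dataclass
class AttributionResult:
    focal: str
    partner: str
    stats: pd.DataFrame  # long: feature_id, day, contrast, log2fc, t, p, padj
    selected: pd.Series  # boolean per feature
    alpha: float
    lfc_min: float

    @property
    def selected_features(self) -> list[str]:
        return list(self.selected.index[self.selected])


def _group_cols(table: PeakTable, focal: str, partner: str, day: int) -> list[str]:
    return list(table.condition_ids(focal, partner, day))


def attribute_producers(
    glog_table: PeakTable,
    norm_table: PeakTable,
    focal: str,
    partner: str,
    alpha: float = 0.05,
    lfc_min: float = 1.5,
    same_day: bool = False,
    allow_decrease: bool = False,
) -> AttributionResult:
    """Run the dual-contrast selection for one (focal, partner) pairing.

    Welch t-tests are computed on the glog table; log2 fold changes on the
    normalized (pre-glog) table's group means. BH adjustment is applied per
    contrast per day across features. ``same_day=True`` requires both
    contrasts to pass on a common day (strict reading); the default accepts
    any day per contrast.
    """
    if not glog_table.features.equals(norm_table.features):
        raise ValueError("glog and normalized tables must share features")
    smeta = glog_table.sample_meta
    days = sorted(smeta.loc[smeta["role"] == "sample", "day"].unique())
    feats = glog_table.features

    missing = []
    for day in days:
        for pair in ((focal, partner), (focal, focal), (partner, focal)):
            if len(_group_cols(glog_table, *pair, day)) < 2:
                missing.append(f"{pair[0]}-{pair[1]} day {day}")
    if missing:
        raise ValueError(
            "need >= 2 replicates for each required group; missing: "
            + ", ".join(missing)
        )

    G = glog_table.intensities
    N = norm_table.intensities
    rows = []
    for day in days:
        xy = _group_cols(glog_table, focal, partner, day)
        ref_groups = {
            "XY_vs_XX": _group_cols(glog_table, focal, focal, day),
            "XY_vs_YX": _group_cols(glog_table, partner, focal, day),
        }
        for contrast, ref in ref_groups.items():
            a = G[xy].to_numpy(dtype=float)
            b = G[ref].to_numpy(dtype=float)
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
            eps = 1e-9
            lfc = np.log2(
                (N[xy].mean(axis=1).to_numpy() + eps)
                / (N[ref].mean(axis=1).to_numpy() + eps)
            )
            padj = bh_adjust(p)
            for i, f in enumerate(feats):
                rows.append(
                    {
                        "feature_id": f,
                        "day": day,
                        "contrast": contrast,
                        "log2fc": lfc[i],
                        "t": t[i],
                        "p": p[i],
                        "padj": padj[i],
                    }
                )
    long = pd.DataFrame(rows)

    passes = long.assign(
        ok=(long["padj"] <= alpha)
        & (
            (long["log2fc"] >= lfc_min)
            | (allow_decrease & (long["log2fc"] <= -lfc_min))
        )
    )
    if same_day:
        per_day = passes.pivot_table(
            index=["feature_id", "day"], columns="contrast", values="ok", aggfunc="any"
        ).reindex(columns=list(CONTRASTS), fill_value=False)
        both = per_day.fillna(False).all(axis=1)
        sel = both.groupby(level="feature_id").any()
    else:
        per_contrast = passes.groupby(["feature_id", "contrast"])["ok"].any().unstack()
        per_contrast = per_contrast.reindex(columns=list(CONTRASTS), fill_value=False)
        sel = per_contrast.fillna(False).all(axis=1)
    selected = sel.reindex(feats, fill_value=False).astype(bool)
    selected.name = "selected"

    return AttributionResult(
        focal=focal, partner=partner, stats=long, selected=selected,
        alpha=alpha, lfc_min=lfc_min,
    )


def attribute_all_pairs(
    glog_table: PeakTable,
    norm_table: PeakTable,
    strains: list[str],
    alpha: float = 0.05,
    lfc_min: float = 1.5,
    **kw,
) -> dict[tuple[str, str], AttributionResult]:
    """Attribution for every ordered pair of distinct strains."""
    out = {}
    for x in strains:
        for y in strains:
            if x == y:
                continue
            out[(x, y)] = attribute_producers(
                glog_table, norm_table, x, y, alpha, lfc_min, **kw
            )
    return out
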