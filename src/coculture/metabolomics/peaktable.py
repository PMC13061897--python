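"""Feature x sample intensity container for LC-MS peak tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sample roles recognised in sample metadata
ROLES = ("sample", "QC", "blank")


@dataclass
class PeakTable:
    """An LC-MS peak table: intensities plus feature and sample metadata.

    Parameters
    ----------
    intensities : DataFrame
        Feature x sample matrix; index = feature ids, columns = sample ids.
        Missing values are NaN; observed values are >= 0.
    feature_meta : DataFrame
        Indexed by feature id with columns ``mz``, ``rt``, ``polarity``.
    sample_meta : DataFrame
        Indexed by sample id with columns ``focal``, ``partner``, ``day``,
        ``replicate``, ``injection_order``, ``batch``, ``role``.
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.feature_meta.index):
            raise ValueError("intensity rows must match feature_meta index")
        if not self.intensities.columns.equals(self.sample_meta.index):
            raise ValueError("intensity columns must match sample_meta index")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be >= 0 or missing")
        bad = set(self.sample_meta["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        for batch, grp in self.sample_meta.groupby("batch"):
            if grp["injection_order"].duplicated().any():
                raise ValueError(f"duplicate injection_order in batch {batch!r}")

    # -- convenience selectors -------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    def sample_ids(self, role: str) -> pd.Index:
        return self.sample_meta.index[self.sample_meta["role"] == role]

    def condition_ids(self, focal: str, partner: str, day: int | None = None) -> pd.Index:
        m = (
            (self.sample_meta["role"] == "sample")
            & (self.sample_meta["focal"] == focal)
            & (self.sample_meta["partner"] == partner)
        )
        if day is not None:
            m &= self.sample_meta["day"] == day
        return self.sample_meta.index[m]

    def with_intensities(self, new: pd.DataFrame, note: str | None = None) -> "PeakTable":
        """Return a copy carrying ``new`` intensities and an extended log."""
        log = list(self.log) + ([note] if note else [])
        return PeakTable(new, self.feature_meta.loc[new.index].copy(),
                         self.sample_meta.copy(), log)

    def subset_features(self, keep: pd.Index, note: str | None = None) -> "PeakTable":
        log = list(self.log) + ([note] if note else [])
        return PeakTable(self.intensities.loc[keep].copy(),
                         self.feature_meta.loc[keep].copy(),
                         self.sample_meta.copy(), log)

    # -- I/O --------------------------------------------------------------
    def to_tsv(self, intensities_path, samples_path) -> None:
        wide = self.feature_meta.join(self.intensities)
        wide.to_csv(intensities_path, sep="\t", index_label="feature_id")
        self.sample_meta.to_csv(samples_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, intensities_path, samples_path) -> "PeakTable":
        wide = pd.read_csv(intensities_path, sep="\t", index_col="feature_id")
        smeta = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
        meta_cols = [c for c in ("mz", "rt", "polarity") if c in wide.columns]
        fmeta = wide[meta_cols]
        inten = wide.drop(columns=meta_cols)
        inten.columns = inten.columns.astype(str)
        smeta.index = smeta.index.astype(str)
        return cls(inten, fmeta, smeta)
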