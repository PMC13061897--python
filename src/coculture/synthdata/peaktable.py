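"""LC-MS peak-table simulation with planted producers, drift and QCs."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ..metabolomics.peaktable import PeakTable
from .design import PlantedTruth, SyntheticDesign


def gen_peaktable(
    design: SyntheticDesign,
    truth: PlantedTruth,
    n_features: int = 200,
    drift_slope: float = 0.0,
    batch_shift: float = 0.0,
    n_batches: int = 1,
    missing_rate: float = 0.0,
    qc_every: int = 6,
    noise_sd: float = 0.2,
    n_blanks: int = 3,
    n_noise_features: int = 0,
    blank_depletion: float = 7.0,
    adduct_pairs: int = 0,
    seed: int | None = None,
) -> PeakTable:
    """Simulate a feature x sample peak table.

    Baselines are log-normal (log2 means uniform in [14, 22], per-cell noise
    SD ``noise_sd`` on the log2 scale). Planted producer features from
    ``truth`` are elevated by their log2 effect in the samples they affect.
    QC samples are noisy replicates of the pooled mean spectrum placed at
    every ``qc_every``-th injection; blanks sit at baseline/2**blank_depletion.
    The last ``n_noise_features`` features are blank-level noise in every
    sample (for blank-ratio filter tests). ``adduct_pairs`` appends, for each
    of the first so-many features, a co-eluting shadow feature with perfectly
    correlated profile at half intensity (for peak-grouping tests).
    Multiplicative injection-order drift has fractional slope ``drift_slope``
    over the run; batch 2..n are shifted by ``batch_shift`` log2 units.
    Missingness is intensity-dependent (probit on log intensity), calibrated
    so the overall missing fraction approximates ``missing_rate``.
    """
    if qc_every < 2:
        raise ValueError("qc_every must be >= 2")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    if len(truth.producer_features) > n_features:
        raise ValueError("n_features must cover all planted features")
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng([seed, 201])

    feature_ids = [f"F{i:04d}" for i in range(n_features)]
    missing_planted = set(truth.producer_features) - set(feature_ids)
    if missing_planted:
        raise ValueError(
            f"planted feature ids not in generated id space: {sorted(missing_planted)}"
        )

    bio = design.sample_labels()
    n_bio = len(bio)
    blanks = [f"blank_r{i+1}" for i in range(n_blanks)]

    base = rng.uniform(14.0, 22.0, size=n_features)  # log2 baseline per feature
    noise_idx = np.zeros(n_features, dtype=bool)
    if n_noise_features:
        noise_idx[-n_noise_features:] = True

    # planted log2 effect per (feature, biological sample)
    effect = np.zeros((n_features, n_bio))
    fid_pos = {f: i for i, f in enumerate(feature_ids)}
    for fid, pf in truth.producer_features.items():
        for j, s in enumerate(bio):
            focal, partner = s.split("_")[0].split("-")
            if pf.affects(focal, partner):
                effect[fid_pos[fid], j] += pf.log2fc

    clean = base[:, None] + effect  # expected log2 intensity, no noise
    clean[noise_idx, :] = (base - blank_depletion)[noise_idx][:, None]
    log2_bio = clean + rng.normal(0.0, noise_sd, size=clean.shape)

    pooled = clean.mean(axis=1)  # pooled QC mean spectrum (log2)

    # interleave QCs among randomized biological injections, blanks at both ends
    order_bio = rng.permutation(n_bio)
    inj_sequence: list[tuple[str, str]] = [("blank", b) for b in blanks[: max(1, n_blanks // 2)]]
    qc_count = 0
    for pos, j in enumerate(order_bio):
        if pos % qc_every == 0:
            qc_count += 1
            inj_sequence.append(("QC", f"QC_{qc_count:02d}"))
        inj_sequence.append(("sample", bio[j]))
    qc_count += 1
    inj_sequence.append(("QC", f"QC_{qc_count:02d}"))
    inj_sequence += [("blank", b) for b in blanks[max(1, n_blanks // 2):]]

    n_inj = len(inj_sequence)
    columns, roles, log2_cols = [], [], []
    for k, (role, name) in enumerate(inj_sequence):
        if role == "sample":
            col = log2_bio[:, bio.index(name)]
        elif role == "QC":
            col = pooled + rng.normal(0.0, noise_sd, size=n_features)
        else:
            col = base - blank_depletion + rng.normal(0.0, noise_sd, size=n_features)
        columns.append(name)
        roles.append(role)
        log2_cols.append(col)
    log2_mat = np.column_stack(log2_cols)

    inj_order = np.arange(1, n_inj + 1)
    batch = np.minimum(((inj_order - 1) * n_batches) // n_inj, n_batches - 1) + 1
    drift = np.log2(1.0 + drift_slope * (inj_order - 1) / max(n_inj - 1, 1))
    log2_mat = log2_mat + drift[None, :] + batch_shift * (batch - 1)[None, :]

    intens = np.power(2.0, log2_mat)

    if missing_rate > 0:
        z = (log2_mat - log2_mat.mean()) / log2_mat.std()
        raw = stats.norm.cdf(-z)  # low intensity -> high missing propensity
        p = np.clip(missing_rate * raw / raw.mean(), 0.0, 0.95)
        intens[rng.random(intens.shape) < p] = np.nan

    fmeta = pd.DataFrame(
        {
            "mz": np.round(rng.uniform(100.0, 1200.0, size=n_features), 4),
            "rt": np.round(rng.uniform(30.0, 600.0, size=n_features), 2),
            "polarity": "+",
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    inten_df = pd.DataFrame(intens, index=fmeta.index, columns=columns)

    if adduct_pairs:
        if adduct_pairs > n_features:
            raise ValueError("adduct_pairs exceeds n_features")
        shadow = inten_df.iloc[:adduct_pairs] * 0.5
        shadow.index = pd.Index(
            [f"F{i:04d}a" for i in range(adduct_pairs)], name="feature_id"
        )
        smeta_shadow = fmeta.iloc[:adduct_pairs].copy()
        smeta_shadow.index = shadow.index
        smeta_shadow["mz"] = smeta_shadow["mz"] + 21.9819  # Na-H style offset
        inten_df = pd.concat([inten_df, shadow])
        fmeta = pd.concat([fmeta, smeta_shadow])

    meta_rows = []
    for k, (role, name) in enumerate(inj_sequence):
        if role == "sample":
            pair, d, r = name.split("_")
            focal, partner = pair.split("-")
            day, rep = int(d[1:]), int(r[1:])
        else:
            focal = partner = ""
            day = rep = -1
        meta_rows.append(
            {
                "sample_id": name,
                "focal": focal,
                "partner": partner,
                "day": day,
                "replicate": rep,
                "injection_order": int(inj_order[k]),
                "batch": int(batch[k]),
                "role": role,
            }
        )
    smeta = pd.DataFrame(meta_rows).set_index("sample_id")

    return PeakTable(inten_df, fmeta, smeta, log=["synthdata.gen_peaktable"])


def default_truth_features(design: SyntheticDesign) -> PlantedTruth:
    """A small default planting: one diffusible producer + one pair-specific."""
    from .design import PlantedFeature

    truth = PlantedTruth()
    strains = design.strains
    truth.producer_features["F0000"] = PlantedFeature(
        producer=strains[min(2, len(strains) - 1)], partner=None,
        log2fc=4.0, diffusible=True,
    )
    if len(strains) >= 3:
        truth.producer_features["F0001"] = PlantedFeature(
            producer=strains[0], partner=strains[2], log2fc=3.0, diffusible=False
        )
    return truth
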