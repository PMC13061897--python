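"""Peak-table preprocessing: filtering, peak grouping, drift correction,
PQN, kNN imputation, glog variance stabilization and row scaling.

The canonical pipeline order is: filter -> group -> drift -> PQN ->
impute -> glog -> statistics. Drift correction and PQN operate on observed
cells only; imputation comes after normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import interpolate, optimize

from .peaktable import PeakTable


def filter_features(
    table: PeakTable,
    min_present_frac: float = 0.5,
    blank_ratio: float | None = 3.0,
) -> PeakTable:
    """Noise/representation filter.

    Keep a feature iff it is observed in at least ``min_present_frac`` of
    replicates of some condition x day group, and (when ``blank_ratio`` is
    set) its mean sample intensity is >= blank_ratio x mean blank intensity.
    """
    I = table.intensities
    smeta = table.sample_meta
    samp = smeta.index[smeta["role"] == "sample"]
    keep = pd.Series(False, index=I.index)
    grp_cols = smeta.loc[samp, ["focal", "partner", "day"]]
    for _, ids in grp_cols.groupby(["focal", "partner", "day"]).groups.items():
        frac = I[list(ids)].notna().mean(axis=1)
        keep |= frac >= min_present_frac

    if blank_ratio is not None:
        blanks = smeta.index[smeta["role"] == "blank"]
        if len(blanks) == 0:
            raise ValueError("blank_ratio filtering requested but table has no blanks")
        blank_mean = I[list(blanks)].mean(axis=1, skipna=True).fillna(0.0)
        samp_mean = I[list(samp)].mean(axis=1, skipna=True).fillna(0.0)
        keep &= samp_mean >= blank_ratio * blank_mean
    return table.subset_features(I.index[keep], note="filter_features")


def group_related_peaks(
    table: PeakTable, rt_window: float = 5.0, min_corr: float = 0.9
) -> PeakTable:
    """Collapse features likely to stem from one molecule.

    Single-linkage clusters of features within ``rt_window`` seconds of
    each other whose observed intensity profiles correlate >= ``min_corr``
    (Pearson, over co-observed samples). The most intense member (highest
    mean) represents each group; membership is retained in feature_meta
    under ``peak_group``.
    """
    I = table.intensities
    if I.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation-based grouping")
    feats = list(I.index)
    rt = table.feature_meta["rt"].to_numpy(dtype=float)
    pol = table.feature_meta["polarity"].to_numpy()
    X = I.to_numpy(dtype=float)

    parent = list(range(len(feats)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = np.argsort(rt, kind="mergesort")
    for a_pos in range(len(order)):
        i = order[a_pos]
        for b_pos in range(a_pos + 1, len(order)):
            j = order[b_pos]
            if rt[j] - rt[i] > rt_window:
                break
            if pol[i] != pol[j]:
                continue
            both = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if both.sum() < 3:
                continue
            xi, xj = X[i][both], X[j][both]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            if np.corrcoef(xi, xj)[0, 1] >= min_corr:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(len(feats)):
        groups.setdefault(find(i), []).append(i)

    mean_int = np.nanmean(X, axis=1)
    reps, labels = [], {}
    for gid, members in groups.items():
        rep = members[int(np.argmax(mean_int[members]))]
        reps.append(rep)
        for m in members:
            labels[feats[m]] = feats[rep]
    keep = I.index[sorted(reps)]
    out = table.subset_features(keep, note="group_related_peaks")
    out.feature_meta = out.feature_meta.copy()
    out.feature_meta["peak_group"] = [labels[f] for f in out.feature_meta.index]
    return out


def drift_correct(table: PeakTable, min_qc: int = 4,
                  spline_min_qc: int = 6) -> PeakTable:
    """QC-anchored signal-drift and batch-effect correction.

    Per feature per batch: fit a smoother of QC intensity vs injection
    order (cubic smoothing spline when >= ``spline_min_qc`` QCs, otherwise
    a linear fit), divide every injection by the interpolated fit and
    rescale to the feature's grand QC median across batches (so step
    offsets between batches are removed too). Features with fewer than
    ``min_qc`` usable QCs in a batch pass through unchanged and are flagged
    in feature_meta[``drift_flagged``].
    """
    I = table.intensities.copy()
    smeta = table.sample_meta
    flagged = pd.Series(False, index=I.index)
    all_qc = smeta.index[smeta["role"] == "QC"]
    with np.errstate(divide="ignore"):
        grand_med = np.log2(table.intensities[list(all_qc)]).median(
            axis=1, skipna=True
        )

    for batch, bmeta in smeta.groupby("batch"):
        cols = bmeta.index
        qc_cols = bmeta.index[bmeta["role"] == "QC"]
        if len(qc_cols) < min_qc:
            flagged[:] = True
            continue
        x_all = bmeta["injection_order"].to_numpy(dtype=float)
        x_qc = bmeta.loc[qc_cols, "injection_order"].to_numpy(dtype=float)
        for f in I.index:
            y_qc = I.loc[f, qc_cols].to_numpy(dtype=float)
            ok = ~np.isnan(y_qc) & (y_qc > 0)
            if ok.sum() < min_qc:
                flagged[f] = True
                continue
            xs, ys = x_qc[ok], np.log2(y_qc[ok])
            if ok.sum() >= spline_min_qc:
                fit = interpolate.make_smoothing_spline(xs, ys)
                trend = np.asarray(fit(x_all))
            else:
                slope, icept = np.polyfit(xs, ys, 1)
                trend = slope * x_all + icept
            med = grand_med[f]
            if not np.isfinite(med):
                med = float(np.median(ys))
            corr = np.power(2.0, trend - med)  # multiplicative trend
            I.loc[f, cols] = I.loc[f, cols].to_numpy(dtype=float) / corr
    out = table.with_intensities(I, note="drift_correct")
    out.feature_meta = out.feature_meta.copy()
    out.feature_meta["drift_flagged"] = flagged
    return out


def pqn_normalize(table: PeakTable, reference: str = "qc") -> PeakTable:
    """Probabilistic quotient normalization.

    The reference spectrum is the feature-wise median over QC samples
    (``reference='qc'``) or over all non-blank samples (``'median'``). Each
    sample is divided by the median of its feature-wise quotients to the
    reference, computed over shared observed features. Dilution factors are
    stored in sample_meta[``pqn_factor``].
    """
    I = table.intensities
    smeta = table.sample_meta
    if reference == "qc":
        ref_cols = smeta.index[smeta["role"] == "QC"]
        if len(ref_cols) == 0:
            raise ValueError("no QC samples for reference='qc'")
    elif reference == "median":
        ref_cols = smeta.index[smeta["role"] != "blank"]
    else:
        raise ValueError("reference must be 'qc' or 'median'")
    ref = I[list(ref_cols)].median(axis=1, skipna=True)

    factors = {}
    out = I.copy()
    for s in I.columns:
        shared = I[s].notna() & ref.notna() & (ref > 0)
        if not shared.any():
            raise ValueError(f"sample {s!r} shares no observed features with reference")
        quot = (I.loc[shared, s] / ref[shared]).to_numpy(dtype=float)
        f = float(np.median(quot))
        if f <= 0:
            raise ValueError(f"non-positive dilution factor for sample {s!r}")
        factors[s] = f
        out[s] = I[s] / f
    res = table.with_intensities(out, note=f"pqn_normalize[{reference}]")
    res.sample_meta = res.sample_meta.copy()
    res.sample_meta["pqn_factor"] = pd.Series(factors)
    return res


def knn_impute(table: PeakTable, k: int = 5) -> PeakTable:
    """k-nearest-neighbour imputation across samples.

    Distance between samples = Euclidean over co-observed features,
    normalized by the number of co-observed features. A missing cell is the
    mean of the k nearest samples with that feature observed (fewer if not
    enough neighbours exist).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    I = table.intensities
    X = np.log2(I.to_numpy(dtype=float) + 1.0)  # distances on log scale
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        bad = I.index[~obs.any(axis=1)].tolist()
        raise ValueError(f"features with no observed value: {bad}")
    n = X.shape[1]
    D = np.full((n, n), np.inf)
    for a in range(n):
        for b in range(a + 1, n):
            both = obs[:, a] & obs[:, b]
            m = int(both.sum())
            if m == 0:
                continue
            d = float(np.sum((X[both, a] - X[both, b]) ** 2) / m)
            D[a, b] = D[b, a] = d

    out = I.to_numpy(dtype=float).copy()
    raw = I.to_numpy(dtype=float)
    for a in range(n):
        miss = np.flatnonzero(~obs[:, a])
        if miss.size == 0:
            continue
        order = np.argsort(D[a], kind="mergesort")
        for f in miss:
            donors = [b for b in order if np.isfinite(D[a, b]) and obs[f, b]][:k]
            if not donors:
                donors = np.flatnonzero(obs[f]).tolist()[:k]
            out[f, a] = float(np.mean(raw[f, donors]))
    res = pd.DataFrame(out, index=I.index, columns=I.columns)
    return table.with_intensities(res, note=f"knn_impute[k={k}]")


def glog(x: np.ndarray, lam: float) -> np.ndarray:
    """Generalised logarithm g(x) = log2((x + sqrt(x^2 + lambda)) / 2)."""
    x = np.asarray(x, dtype=float)
    return np.log2((x + np.sqrt(x**2 + lam)) / 2.0)


def _sd_mean_slope(X: np.ndarray, lam: float, n_bins: int = 10) -> float:
    G = glog(X, lam)
    mu = G.mean(axis=1)
    sd = G.std(axis=1, ddof=1)
    order = np.argsort(mu)
    bins = np.array_split(order, n_bins)
    bm = np.array([mu[b].mean() for b in bins if len(b)])
    bs = np.array([sd[b].mean() for b in bins if len(b)])
    if len(bm) < 2 or np.std(bm) == 0:
        return 0.0
    return float(np.polyfit(bm, bs, 1)[0])


def glog_transform(table: PeakTable, lam: float | str = "auto") -> PeakTable:
    """Variance-stabilizing glog transform.

    ``lam='auto'`` picks the lambda minimizing |slope| of the SD-vs-mean
    relationship across feature bins, computed on QC samples when present
    (else all samples), via bounded 1-D search on log10(lambda). The chosen
    lambda is recorded in the log.
    """
    I = table.intensities
    if I.isna().any().any():
        raise ValueError("glog requires a complete table; impute first")
    if (I.to_numpy() < 0).any():
        raise ValueError("glog requires intensities >= 0")
    if lam == "auto":
        qc = table.sample_meta.index[table.sample_meta["role"] == "QC"]
        cols = list(qc) if len(qc) >= 3 else list(I.columns)
        X = I[cols].to_numpy(dtype=float)
        scale = float(np.nanmedian(X[X > 0])) if (X > 0).any() else 1.0

        def objective(log10_lam: float) -> float:
            return abs(_sd_mean_slope(X, 10.0**log10_lam))

        lo, hi = np.log10(scale**2) - 8, np.log10(scale**2) + 8
        res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded")
        lam_val = float(10.0**res.x)
    else:
        lam_val = float(lam)
        if lam_val < 0:
            raise ValueError("lambda must be >= 0")
    out = pd.DataFrame(glog(I.to_numpy(dtype=float), lam_val),
                       index=I.index, columns=I.columns)
    return table.with_intensities(out, note=f"glog[lambda={lam_val:.6g}]")


def row_zscore(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-scale to Z-scores (mean 0, SD 1, ddof=1 denominator).

    Constant rows come back all-zero and flagged in the returned Series.
    """
    X = matrix.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    Z[flat, :] = 0.0
    return (
        pd.DataFrame(Z, index=matrix.index, columns=matrix.columns),
        pd.Series(flat, index=matrix.index, name="constant_row"),
    )


def qc_rsd(table: PeakTable) -> pd.Series:
    """Per-feature relative SD across QC injections (drift diagnostics)."""
    qc = table.sample_meta.index[table.sample_meta["role"] == "QC"]
    sub = table.intensities[list(qc)]
    return (sub.std(axis=1, ddof=1) / sub.mean(axis=1)).rename("qc_rsd")


def run_preprocessing(
    table: PeakTable,
    min_present_frac: float = 0.5,
    blank_ratio: float | None = 3.0,
    rt_window: float = 5.0,
    min_corr: float = 0.9,
    knn_k: int = 5,
    lam: float | str = "auto",
) -> tuple[PeakTable, PeakTable]:
    """Full pipeline in the fixed order; returns (normalized, glog) tables.

    The normalized table (post-PQN, post-imputation, pre-glog) is what fold
    changes are computed on; the glog table feeds the t-tests.
    """
    t = filter_features(table, min_present_frac, blank_ratio)
    t = group_related_peaks(t, rt_window, min_corr)
    t = drift_correct(t)
    t = pqn_normalize(t)
    t = knn_impute(t, knn_k)
    g = glog_transform(t, lam)
    return t, g
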