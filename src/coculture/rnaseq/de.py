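"""Simplified negative-binomial differential expression.

This is intentionally NOT a DESeq2 reimplementation: dispersions come from
a moderated method-of-moments estimator (per-gene estimates shrunk toward
the pooled central value, with a floor), there is no LFC shrinkage and no
outlier filtering. Wald mode tests a two-level group factor; LRT mode
compares the full partner + day + partner:day model against the day-only
reduced model, per the experimental design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .._stats import bh_adjust
from .normalize import normalized_counts, size_factors

MIN_DISP = 1e-8


def _dispersion_moments(q: pd.DataFrame, groups: pd.Series,
                        mean_inv_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene method-of-moments dispersion from within-group residuals.

    Returns (alpha_mom, residual_df). Uses E[var_within] = mu/s~ + alpha*mu^2
    on median-of-ratios-normalized counts.
    """
    Q = q.to_numpy(dtype=float)
    lvls = groups.unique()
    ss = np.zeros(Q.shape[0])
    df = 0
    for lv in lvls:
        cols = np.flatnonzero((groups == lv).to_numpy())
        if cols.size < 2:
            continue
        sub = Q[:, cols]
        ss += sub.var(axis=1, ddof=1) * (cols.size - 1)
        df += cols.size - 1
    if df == 0:
        raise ValueError("need >= 2 replicates in at least one group")
    var_w = ss / df
    mu = Q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_w - mu * mean_inv_s) / mu**2
    return alpha, np.full(Q.shape[0], float(df))


def _moderate_dispersion(alpha_mom: np.ndarray, df: np.ndarray,
                         prior_df: float = 20.0) -> np.ndarray:
    """Shrink per-gene moment dispersions toward the pooled central value."""
    finite = np.isfinite(alpha_mom)
    if finite.any():
        central = float(np.nanmean(np.clip(alpha_mom[finite], 0, None)))
    else:
        central = MIN_DISP
    central = max(central, MIN_DISP)
    a = np.where(np.isfinite(alpha_mom), np.clip(alpha_mom, 0, None), central)
    shrunk = (df * a + prior_df * central) / (df + prior_df)
    return np.clip(shrunk, MIN_DISP, None)


def differential_expression(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    mode: str = "wald",
    group_col: str = "group",
    levels: tuple[str, str] | None = None,
    partner_col: str = "partner",
    day_col: str = "day",
    min_base_mean: float = 0.5,
    prior_df: float = 20.0,
    pseudo_reference: bool = False,
) -> pd.DataFrame:
    """Run the NB test over a gene x sample count matrix.

    Returns a per-gene table: baseMean, log2FoldChange, lfcSE, stat, pvalue,
    padj, status. Genes below ``min_base_mean`` normalized mean (the
    independent-filtering floor) or with zero variance are excluded from
    testing (pvalue/padj NaN, status set accordingly).
    """
    if not counts.columns.equals(meta.index):
        meta = meta.loc[counts.columns]
    counts = counts.loc[(counts != 0).any(axis=1)]
    s = size_factors(counts, pseudo_reference=pseudo_reference)
    q = normalized_counts(counts, s)
    mean_inv_s = float((1.0 / s).mean())

    if mode == "wald":
        return _wald(counts, q, meta, s, group_col, levels, min_base_mean,
                     prior_df, mean_inv_s)
    if mode == "lrt":
        return _lrt(counts, q, meta, s, partner_col, day_col, min_base_mean,
                    prior_df, mean_inv_s)
    raise ValueError(f"unknown mode {mode!r}")


def _wald(counts, q, meta, s, group_col, levels, min_base_mean, prior_df,
          mean_inv_s) -> pd.DataFrame:
    groups = meta[group_col].astype(str)
    if levels is None:
        lv = list(pd.unique(groups))
        if len(lv) != 2:
            raise ValueError("wald mode needs exactly two group levels")
        levels = (lv[0], lv[1])
    ref, alt = levels
    c1 = np.flatnonzero((groups == ref).to_numpy())
    c2 = np.flatnonzero((groups == alt).to_numpy())
    if min(c1.size, c2.size) < 2:
        raise ValueError("need >= 2 replicates per group")

    Q = q.to_numpy(dtype=float)
    mu1, mu2 = Q[:, c1].mean(axis=1), Q[:, c2].mean(axis=1)
    base_mean = Q.mean(axis=1)

    alpha_mom, df = _dispersion_moments(q, groups, mean_inv_s)
    alpha = _moderate_dispersion(alpha_mom, df, prior_df)

    var_w = np.zeros(Q.shape[0])
    for cols in (c1, c2):
        var_w += Q[:, cols].var(axis=1, ddof=1) * (cols.size - 1)
    # relative tolerance absorbs float noise from size-factor division
    zero_var = (var_w <= 1e-20 * np.maximum(base_mean, 1.0) ** 2) & (
        np.abs(mu1 - mu2) <= 1e-10 * np.maximum(base_mean, 1.0)
    )

    eps = 1e-9
    testable = (base_mean >= min_base_mean) & (mu1 + mu2 > 0) & ~zero_var

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2((mu2 + eps) / (mu1 + eps))
        v1 = mu1 * mean_inv_s + alpha * mu1**2
        v2 = mu2 * mean_inv_s + alpha * mu2**2
        se_ln = np.sqrt(
            v1 / (c1.size * np.maximum(mu1, eps) ** 2)
            + v2 / (c2.size * np.maximum(mu2, eps) ** 2)
        )
        lfc_se = se_ln / np.log(2)
        z = log2fc / lfc_se
    pvalue = np.where(testable, 2 * stats.norm.sf(np.abs(z)), np.nan)
    padj = bh_adjust(pvalue)

    status = np.where(zero_var, "zero_variance",
                      np.where(testable, "tested", "low_count"))
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": lfc_se,
            "stat": z,
            "pvalue": pvalue,
            "padj": padj,
            "status": status,
        },
        index=counts.index,
    )


def _design_matrix(meta: pd.DataFrame, cols: list[str],
                   interaction: bool) -> np.ndarray:
    """Treatment-coded design matrix with optional pairwise interaction."""
    parts = [np.ones((len(meta), 1))]
    dummies = []
    for c in cols:
        d = pd.get_dummies(meta[c].astype(str), drop_first=True, dtype=float)
        dummies.append(d.to_numpy())
        parts.append(d.to_numpy())
    if interaction and len(cols) == 2:
        a, b = dummies
        inter = np.einsum("ij,ik->ijk", a, b).reshape(len(meta), -1)
        parts.append(inter)
    return np.concatenate(parts, axis=1)


def _lrt(counts, q, meta, s, partner_col, day_col, min_base_mean, prior_df,
         mean_inv_s) -> pd.DataFrame:
    import statsmodels.api as sm

    cell = meta[partner_col].astype(str) + "|" + meta[day_col].astype(str)
    alpha_mom, df = _dispersion_moments(q, cell, mean_inv_s)
    alpha = _moderate_dispersion(alpha_mom, df, prior_df)

    X_full = _design_matrix(meta, [partner_col, day_col], interaction=True)
    X_red = _design_matrix(meta, [day_col], interaction=False)
    df_diff = np.linalg.matrix_rank(X_full) - np.linalg.matrix_rank(X_red)
    offset = np.log(s.to_numpy())

    Q = q.to_numpy(dtype=float)
    base_mean = Q.mean(axis=1)
    # report the largest partner-vs-self fold change on normalized means
    partners = meta[partner_col].astype(str)
    plevels = list(pd.unique(partners))
    pmeans = {p: Q[:, (partners == p).to_numpy()].mean(axis=1) for p in plevels}
    ref_p = plevels[0]
    eps = 1e-9
    lfc_all = np.column_stack(
        [np.log2((pmeans[p] + eps) / (pmeans[ref_p] + eps)) for p in plevels[1:]]
    )
    idx = np.argmax(np.abs(lfc_all), axis=1)
    log2fc = lfc_all[np.arange(len(counts)), idx]

    K = counts.to_numpy(dtype=float)
    n_genes = K.shape[0]
    stat = np.full(n_genes, np.nan)
    pvalue = np.full(n_genes, np.nan)
    status = np.full(n_genes, "tested", dtype=object)
    for i in range(n_genes):
        if base_mean[i] < min_base_mean:
            status[i] = "low_count"
            continue
        if K[i].var() == 0:
            status[i] = "zero_variance"
            continue
        fam = sm.families.NegativeBinomial(alpha=max(alpha[i], MIN_DISP))
        try:
            full = sm.GLM(K[i], X_full, family=fam, offset=offset).fit()
            red = sm.GLM(K[i], X_red, family=fam, offset=offset).fit()
            lr = 2.0 * (full.llf - red.llf)
            stat[i] = max(lr, 0.0)
            pvalue[i] = stats.chi2.sf(stat[i], df_diff)
        except Exception:
            status[i] = "fit_failed"
    padj = bh_adjust(pvalue)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": log2fc,
            "lfcSE": np.nan,
            "stat": stat,
            "pvalue": pvalue,
            "padj": padj,
            "status": status,
        },
        index=counts.index,
    )


def significant_genes(de: pd.DataFrame, padj_max: float = 0.05,
                      lfc_min: float = 1.0) -> pd.DataFrame:
    """DE calls used as enrichment input (padj <= 0.05, |log2FC| > 1)."""
    m = (de["padj"] <= padj_max) & (de["log2FoldChange"].abs() > lfc_min)
    return de[m.fillna(False)]


def volcano_flags(de: pd.DataFrame, padj_max: float = 0.05,
                  lfc_min: float = 2.0) -> pd.Series:
    """Volcano-plot significance flags (padj < 0.05 and |log2FC| > 2)."""
    return ((de["padj"] < padj_max) & (de["log2FoldChange"].abs() > lfc_min)).fillna(False)
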