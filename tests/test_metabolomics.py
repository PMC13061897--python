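import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_bh
from coculture._stats import bh_adjust
from coculture.metabolomics import (
    DFO_B,
    IonTarget,
    PeakTable,
    adduct_mz,
    attribute_producers,
    drift_correct,
    filter_features,
    glog,
    glog_transform,
    group_related_peaks,
    knn_impute,
    match_known_ions,
    monoisotopic_mass,
    parse_formula,
    pqn_normalize,
    qc_rsd,
    row_zscore,
    run_preprocessing,
)
from coculture.synthdata import (
    PlantedFeature,
    PlantedTruth,
    SyntheticDesign,
    gen_peaktable,
)


def _mini_table(intens: np.ndarray, roles=None, **meta_extra) -> PeakTable:
    n_feat, n_samp = intens.shape
    fmeta = pd.DataFrame(
        {"mz": np.linspace(100, 900, n_feat), "rt": np.linspace(60, 400, n_feat),
         "polarity": "+"},
        index=pd.Index([f"F{i:04d}" for i in range(n_feat)], name="feature_id"),
    )
    roles = roles or ["sample"] * n_samp
    smeta = pd.DataFrame(
        {
            "focal": ["A" if r == "sample" else "" for r in roles],
            "partner": ["A" if r == "sample" else "" for r in roles],
            "day": [2 if r == "sample" else -1 for r in roles],
            "replicate": list(range(1, n_samp + 1)),
            "injection_order": list(range(1, n_samp + 1)),
            "batch": 1,
            "role": roles,
        },
        index=pd.Index([f"s{i}" for i in range(n_samp)], name="sample_id"),
    )
    for k, v in meta_extra.items():
        smeta[k] = v
    return PeakTable(pd.DataFrame(intens, index=fmeta.index, columns=smeta.index),
                     fmeta, smeta)


class TestBH:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            p = rng.random(rng.integers(1, 60))
            assert np.max(np.abs(bh_adjust(p) - brute_force_bh(p))) < 1e-12

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.random(200)
        ours = bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_property_vs_oracle(self, pvals):
        p = np.array(pvals)
        assert np.max(np.abs(bh_adjust(p) - brute_force_bh(p))) < 1e-12


class TestFilterFeatures:
    def test_present_everywhere_absent_blanks_kept(self):
        X = np.vstack([np.full(8, 1e6), np.full(8, 1e6)])
        X[1, :6] = np.nan  # only observed in blanks
        X[0, 6:] = 100.0  # low in blanks
        X[1, 6:] = 1e6
        t = _mini_table(X, roles=["sample"] * 6 + ["blank"] * 2)
        out = filter_features(t, min_present_frac=0.5, blank_ratio=3)
        assert list(out.features) == ["F0000"]

    def test_blank_level_noise_removed_exactly(self, design2):
        t = gen_peaktable(design2, PlantedTruth(), n_features=100,
                          n_noise_features=30, seed=6)
        out = filter_features(t, min_present_frac=0.5, blank_ratio=3)
        kept = set(out.features)
        noise = {f"F{i:04d}" for i in range(70, 100)}
        assert kept == {f"F{i:04d}" for i in range(70)}
        assert kept.isdisjoint(noise)


class TestGroupRelatedPeaks:
    def test_most_intense_representative(self):
        base = np.exp(np.random.default_rng(0).normal(14, 1, size=6))
        X = np.vstack([base * 2, base])
        t = _mini_table(X)
        t.feature_meta["rt"] = [100.0, 101.0]
        out = group_related_peaks(t, rt_window=5, min_corr=0.9)
        assert list(out.features) == ["F0000"]

    def test_distant_rt_never_grouped(self):
        base = np.exp(np.random.default_rng(0).normal(14, 1, size=6))
        t = _mini_table(np.vstack([base * 2, base]))
        t.feature_meta["rt"] = [100.0, 300.0]
        out = group_related_peaks(t, rt_window=5, min_corr=0.9)
        assert len(out.features) == 2

    def test_planted_adducts_collapse_to_molecule_count(self, design2):
        t = gen_peaktable(design2, PlantedTruth(), n_features=30,
                          adduct_pairs=10, seed=8)
        # shadows share rt and perfectly correlated profiles with parents
        t.feature_meta.loc[[f"F{i:04d}a" for i in range(10)], "rt"] = (
            t.feature_meta.loc[[f"F{i:04d}" for i in range(10)], "rt"].to_numpy()
        )
        out = group_related_peaks(t, rt_window=2, min_corr=0.95)
        assert len(out.features) == 30
        assert not any(f.endswith("a") for f in out.features)


class TestDriftCorrect:
    def test_zero_slope_identity(self, design2):
        t = gen_peaktable(design2, PlantedTruth(), n_features=20,
                          drift_slope=0.0, noise_sd=0.05, seed=3)
        out = drift_correct(t)
        a = t.intensities.to_numpy()
        b = out.intensities.to_numpy()
        assert np.nanmedian(np.abs(b / a - 1)) < 0.05

    def test_reduces_qc_rsd_under_drift(self, design2):
        t = gen_peaktable(design2, PlantedTruth(), n_features=30,
                          drift_slope=1.0, noise_sd=0.1, seed=3)
        pre = qc_rsd(t).median()
        out = drift_correct(t)
        post = qc_rsd(out).median()
        assert post < pre

    def test_batch_step_offset_removed(self, design2):
        t = gen_peaktable(design2, PlantedTruth(), n_features=30, n_batches=2,
                          batch_shift=1.0, noise_sd=0.05, qc_every=3, seed=7)
        out = drift_correct(t)
        qc = out.sample_meta["role"] == "QC"
        b1 = out.sample_meta.index[qc & (out.sample_meta["batch"] == 1)]
        b2 = out.sample_meta.index[qc & (out.sample_meta["batch"] == 2)]
        m1 = out.intensities[list(b1)].median(axis=1)
        m2 = out.intensities[list(b2)].median(axis=1)
        assert float((m2 / m1).median()) == pytest.approx(1.0, abs=0.05)

    def test_too_few_qcs_passthrough_flagged(self):
        X = np.exp(np.random.default_rng(0).normal(14, 1, (5, 8)))
        t = _mini_table(X, roles=["sample"] * 6 + ["QC"] * 2)
        out = drift_correct(t)
        assert out.feature_meta["drift_flagged"].all()
        assert np.allclose(out.intensities, t.intensities)


class TestPQN:
    def _table_with_qc(self, seed=0, n_feat=30, n_samp=6):
        rng = np.random.default_rng(seed)
        X = np.exp(rng.normal(14, 1, (n_feat, n_samp + 2)))
        X[:, -2:] = X[:, :n_samp].mean(axis=1, keepdims=True)
        return _mini_table(X, roles=["sample"] * n_samp + ["QC"] * 2)

    def test_sample_equal_to_reference_unchanged(self):
        t = self._table_with_qc()
        ref = t.intensities[["s6", "s7"]].median(axis=1)
        t.intensities["s0"] = ref
        out = pqn_normalize(t)
        assert out.sample_meta.loc["s0", "pqn_factor"] == pytest.approx(1.0)
        assert np.allclose(out.intensities["s0"], ref)

    def test_3x_dilution_removed(self):
        t = self._table_with_qc()
        ref = t.intensities[["s6", "s7"]].median(axis=1)
        t.intensities["s1"] = 3 * ref
        out = pqn_normalize(t)
        assert out.sample_meta.loc["s1", "pqn_factor"] == pytest.approx(3.0)
        assert np.allclose(out.intensities["s1"], ref)

    def test_idempotence(self):
        t = self._table_with_qc(seed=5)
        once = pqn_normalize(t)
        twice = pqn_normalize(once)
        assert np.allclose(twice.sample_meta["pqn_factor"], 1.0, atol=1e-9)

    def test_scale_equivariance(self):
        t = self._table_with_qc(seed=2)
        out1 = pqn_normalize(t)
        t2 = PeakTable(t.intensities.copy(), t.feature_meta.copy(),
                       t.sample_meta.copy())
        t2.intensities["s3"] *= 17.0
        out2 = pqn_normalize(t2)
        assert np.allclose(out1.intensities["s3"], out2.intensities["s3"])


class TestKnnImpute:
    def test_no_missing_identity(self):
        X = np.exp(np.random.default_rng(0).normal(14, 1, (10, 6)))
        t = _mini_table(X)
        out = knn_impute(t, k=3)
        assert np.allclose(out.intensities, t.intensities)

    def test_twin_sample_k1(self):
        X = np.exp(np.random.default_rng(1).normal(14, 1, (10, 5)))
        X[:, 1] = X[:, 0]  # twin
        X[3, 1] = np.nan
        t = _mini_table(X)
        out = knn_impute(t, k=1)
        assert out.intensities.iloc[3, 1] == pytest.approx(X[3, 0])

    def test_mask_and_recover(self, design2):
        t = gen_peaktable(design2, PlantedTruth(), n_features=60,
                          noise_sd=0.15, seed=10)
        rng = np.random.default_rng(4)
        I = t.intensities.to_numpy().copy()
        mask = rng.random(I.shape) < 0.1
        truth_vals = I[mask]
        I2 = I.copy()
        I2[mask] = np.nan
        t2 = t.with_intensities(pd.DataFrame(I2, index=t.features, columns=t.samples))
        out = knn_impute(t2, k=3)
        rec = out.intensities.to_numpy()[mask]
        rel_err = np.median(np.abs(rec - truth_vals) / truth_vals)
        # baseline: impute with the feature's global mean
        feat_mean = np.nanmean(I2, axis=1)
        base = np.abs(feat_mean[np.nonzero(mask)[0]] - truth_vals) / truth_vals
        assert rel_err < np.median(base)
        assert not out.intensities.isna().any().any()

    def test_all_missing_feature_rejected(self):
        X = np.exp(np.random.default_rng(0).normal(14, 1, (4, 5)))
        X[2, :] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            knn_impute(_mini_table(X), k=2)


class TestGlog:
    def test_lambda_zero_is_log2(self):
        x = np.array([1.0, 10.0, 1e4, 3.7e6])
        assert np.allclose(glog(x, 0.0), np.log2(x))

    @given(
        st.floats(min_value=0.01, max_value=1e8),
        st.floats(min_value=0.011, max_value=1e8),
        st.floats(min_value=0, max_value=1e12),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone(self, x1, x2, lam):
        lo, hi = sorted((x1, x2))
        if lo == hi:
            return
        assert glog(lo, lam) < glog(hi, lam)

    def test_negative_lambda_rejected(self):
        X = np.exp(np.random.default_rng(0).normal(14, 1, (5, 5)))
        with pytest.raises(ValueError, match="lambda"):
            glog_transform(_mini_table(X), lam=-1.0)

    def test_auto_reduces_sd_vs_mean_slope(self):
        rng = np.random.default_rng(6)
        n_feat, n_samp = 200, 12
        mu = np.exp(rng.normal(13, 2, n_feat))
        X = mu[:, None] * np.exp(rng.normal(0, 0.3, (n_feat, n_samp)))
        t = _mini_table(X)
        from coculture.metabolomics.preprocess import _sd_mean_slope

        raw_slope = abs(_sd_mean_slope(X, 0.0))
        out = glog_transform(t, lam="auto")
        lam = float(out.log[-1].split("lambda=")[1].rstrip("]"))
        post_slope = abs(_sd_mean_slope(X, lam))
        assert post_slope <= 0.5 * raw_slope


class TestRowZscore:
    def test_hand_example(self):
        Z, flags = row_zscore(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(Z.to_numpy(), [[-1.0, 0.0, 1.0]])
        assert not flags.iloc[0]

    def test_constant_row_flagged_zero(self):
        Z, flags = row_zscore(pd.DataFrame([[5.0, 5.0, 5.0]]))
        assert np.allclose(Z.to_numpy(), 0.0)
        assert flags.iloc[0]

    def test_row_means_zero(self):
        rng = np.random.default_rng(0)
        Z, _ = row_zscore(pd.DataFrame(rng.normal(3, 2, (20, 8))))
        assert np.abs(Z.mean(axis=1)).max() < 1e-12
        assert np.allclose(Z.std(axis=1, ddof=1), 1.0)


class TestAdductMz:
    def test_dfo_b_doubly_protonated(self):
        assert adduct_mz("C25H48N6O8", "[M+2H]2+") == 281.184

    def test_water_protonated(self):
        assert adduct_mz("H2O", "[M+H]+") == 19.018

    @given(st.sampled_from(["C6H12O6", "C10H14N2", "H2O", "C25H48N6O8", "C2H5NO2"]))
    @settings(max_examples=20, deadline=None)
    def test_proton_mass_difference(self, formula):
        from coculture.metabolomics.masses import PROTON

        M = monoisotopic_mass(formula)
        # full-precision difference rounds to the proton mass
        assert round((M + PROTON) - M, 3) == 1.007
        assert adduct_mz(formula, "[M+H]+") == pytest.approx(M + PROTON, abs=5e-4)

    def test_formula_parser(self):
        assert parse_formula("C25H48N6O8") == {"C": 25, "H": 48, "N": 6, "O": 8}
        with pytest.raises(ValueError, match="unknown element"):
            parse_formula("C2Xx5")

    def test_unknown_adduct(self):
        with pytest.raises(ValueError, match="unsupported adduct"):
            adduct_mz("H2O", "[M+NH4]+")


class TestMatchKnownIons:
    def _table_at(self, mz, polarity="+"):
        X = np.exp(np.random.default_rng(0).normal(14, 1, (1, 4)))
        t = _mini_table(X)
        t.feature_meta["mz"] = [mz]
        t.feature_meta["polarity"] = polarity
        return t

    def test_exact_match(self):
        hits = match_known_ions(self._table_at(281.184), [DFO_B], tol_ppm=10)
        assert len(hits) == 1 and hits.iloc[0]["adduct"] == "[M+2H]2+"

    def test_one_dalton_off_no_match(self):
        hits = match_known_ions(self._table_at(282.184), [DFO_B], tol_ppm=10)
        assert hits.empty

    def test_tight_tolerance_excludes(self):
        mz = 281.184 * (1 + 5e-6)  # 5 ppm off
        hits = match_known_ions(self._table_at(mz), [DFO_B], tol_ppm=0.1)
        assert hits.empty

    def test_polarity_must_agree(self):
        t = self._table_at(19.018, polarity="-")
        hits = match_known_ions(t, [IonTarget("water", "H2O", ("[M+H]+",))],
                                tol_ppm=10)
        assert hits.empty


class TestAttribution:
    def test_flat_table_nothing_selected(self, design2):
        t = gen_peaktable(design2, PlantedTruth(), n_features=40, seed=20)
        norm, gl = run_preprocessing(t, lam=1.0)
        res = attribute_producers(gl, norm, "A", "C")
        assert res.selected_features == []

    def test_planted_feature_recovered_directionally(self, design2, planted_truth2,
                                                     peaktable2):
        norm, gl = run_preprocessing(peaktable2)
        res_ac = attribute_producers(gl, norm, "A", "C")
        res_ca = attribute_producers(gl, norm, "C", "A")
        assert "F0000" in res_ac.selected_features
        assert "F0000" not in res_ca.selected_features

    def test_diffusible_confound_never_selected(self, design2, peaktable2):
        norm, gl = run_preprocessing(peaktable2)
        for focal, partner in (("A", "C"), ("C", "A")):
            res = attribute_producers(gl, norm, focal, partner)
            assert "F0001" not in res.selected_features

    def test_missing_group_raises(self, design2, peaktable2):
        norm, gl = run_preprocessing(peaktable2)
        with pytest.raises(ValueError, match="B-A"):
            attribute_producers(gl, norm, "B", "A")

    def test_padj_ge_p(self, design2, peaktable2):
        norm, gl = run_preprocessing(peaktable2)
        res = attribute_producers(gl, norm, "A", "C")
        ok = res.stats.dropna(subset=["p"])
        assert (ok["padj"] >= ok["p"] - 1e-12).all()

    def test_pipeline_order_logged(self, peaktable2):
        norm, gl = run_preprocessing(peaktable2)
        joined = ";".join(gl.log)
        for step in ("filter_features", "group_related_peaks", "drift_correct",
                     "pqn_normalize", "knn_impute", "glog"):
            assert step in joined
        order = [joined.index(s) for s in ("filter_features", "drift_correct",
                                           "pqn_normalize", "knn_impute", "glog")]
        assert order == sorted(order)
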