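"""Wild-type reference z-test DE, BH correction, imputation and QC."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import proteoscan as ps


# -- WT reference -------------------------------------------------------------

def _wt_matrix(values_by_protein, manifest):
    wt = manifest.samples_of_type("wt_biological")
    df = pd.DataFrame(np.nan, index=list(values_by_protein),
                      columns=manifest.sample_ids)
    for prot, vals in values_by_protein.items():
        df.loc[prot, wt[: len(vals)]] = vals
    return ps.IntensityMatrix(df, scale="normalized")


def test_wt_reference_mean_sd_and_thresholds():
    manifest = ps.build_layout(24, 3)
    m = _wt_matrix({"a": [1.0, 2.0, 3.0], "b": [5.0], "c": [4.0, 4.0, 4.0]},
                   manifest)
    ref = ps.build_wt_reference(m, manifest, min_n=3)
    assert ref.table.loc["a", "mean"] == pytest.approx(2.0)
    assert ref.table.loc["a", "sd"] == pytest.approx(1.0)  # n-1 denominator
    assert ref.table.loc["a", "testable"]
    assert not ref.table.loc["b", "testable"]  # 1 observation < min_n
    assert ref.table.loc["c", "degenerate"]    # zero variance
    assert not ref.table.loc["c", "testable"]


def test_wt_reference_requires_wt_samples():
    manifest = ps.build_layout(8, 1)
    ko_only = ps.IntensityMatrix(
        pd.DataFrame([[1.0]], index=["p"], columns=[
            manifest.samples_of_type("knockout")[0]]), scale="normalized")
    with pytest.raises(ps.ValidationError):
        ps.build_wt_reference(ko_only, manifest)


# -- z-test -------------------------------------------------------------------

def test_ztest_null_and_closed_form_values():
    manifest = ps.build_layout(8, 12)
    wt = manifest.samples_of_type("wt_biological")
    ko = manifest.frame.query("sample_type == 'knockout'")
    rng = np.random.default_rng(0)
    df = pd.DataFrame(np.nan, index=["a"], columns=manifest.sample_ids)
    # reference: mean 10, sd 2 (constructed exactly)
    base = np.array([8.0, 12.0] * 6)
    base = 10.0 + (base - base.mean()) * (2.0 / base.std(ddof=1))
    df.loc["a", wt] = base
    df.loc["a", ko["sample_id"].iloc[0]] = 10.0   # x = mu
    df.loc["a", ko["sample_id"].iloc[1]] = 14.0   # z = 2
    m = ps.IntensityMatrix(df, scale="normalized")
    ref = ps.build_wt_reference(m, manifest, min_n=10)
    de = ps.ztest_de(m, manifest, ref)
    t = de.table.set_index("sample_id")
    s0, s1 = ko["sample_id"].iloc[0], ko["sample_id"].iloc[1]
    assert t.loc[s0, "z"] == pytest.approx(0.0, abs=1e-12)
    assert t.loc[s0, "p"] == pytest.approx(1.0)
    assert t.loc[s1, "z"] == pytest.approx(2.0)
    assert t.loc[s1, "p"] == pytest.approx(0.04550, abs=1e-5)
    assert (t["altered"] == (t["q"] < 0.05)).all()


def test_ztest_skips_degenerate_proteins_with_warning():
    manifest = ps.build_layout(8, 12)
    wt = manifest.samples_of_type("wt_biological")
    ko_sample = manifest.frame.query("sample_type == 'knockout'")["sample_id"].iloc[0]
    df = pd.DataFrame(np.nan, index=["flat"], columns=manifest.sample_ids)
    df.loc["flat", wt] = 3.0
    df.loc["flat", ko_sample] = 9.0
    m = ps.IntensityMatrix(df, scale="normalized")
    ref = ps.build_wt_reference(m, manifest, min_n=10)
    with pytest.warns(UserWarning, match="zero-variance"):
        de = ps.ztest_de(m, manifest, ref)
    assert len(de.table) == 0


def test_ztest_pvalues_uniform_under_null():
    rng = np.random.default_rng(12)
    z = rng.normal(size=10_000)
    p = 2.0 * stats.norm.sf(np.abs(z))
    assert stats.kstest(p, "uniform").pvalue > 0.01


# -- BH FDR -------------------------------------------------------------------

def _bh_oracle(p):
    """Independent step-up implementation: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_bh_worked_example_and_singleton():
    np.testing.assert_allclose(ps.bh_fdr([0.03]), [0.03])
    q = ps.bh_fdr([0.005, 0.011, 0.02, 0.04])
    np.testing.assert_allclose(q, [0.02, 0.022, 0.02 * 4 / 3, 0.04], atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ps.ValidationError):
        ps.bh_fdr([0.5, 1.2])
    with pytest.raises(ps.ValidationError):
        ps.bh_fdr([-0.1])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.sampled_from([0.0, 0.001, 0.005, 0.011, 0.02, 0.04, 0.05,
                                 0.2, 0.5, 0.77, 1.0]),
                min_size=1, max_size=6))
def test_bh_matches_brute_force_oracle(p):
    q = ps.bh_fdr(p)
    np.testing.assert_allclose(q, _bh_oracle(p), atol=1e-9)
    assert (q >= np.asarray(p) - 1e-12).all()  # q >= p elementwise


# -- t-test mode --------------------------------------------------------------

def test_ttest_de_values_and_thresholds():
    a = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["p"])
    b = pd.DataFrame([[3.0, 4.0, 5.0, 6.0]], index=["p"])
    out = ps.ttest_de(a, b)
    assert out.loc["p", "t"] == pytest.approx(-2.190890, abs=1e-5)
    # closed form: 2 * t.sf(2.190890, df=6)
    assert out.loc["p", "p"] == pytest.approx(0.0709876, abs=1e-6)
    assert out.loc["p", "log2fc"] == pytest.approx(-2.0)
    # identical means, nonzero variance -> t = 0, p = 1, not altered
    same = ps.ttest_de(a, a + pd.DataFrame([[0.0, 0.0, 0.0, 0.0]], index=["p"]))
    assert same.loc["p", "t"] == pytest.approx(0.0)
    assert same.loc["p", "p"] == pytest.approx(1.0)
    assert not same.loc["p", "altered"]
    with pytest.raises(ps.ValidationError):
        ps.ttest_de(a.iloc[:, :1], b)


def test_ttest_p_gate_blocks_large_fold_change():
    # log2FC 0.3 but p ~ 0.05: fails the p < 0.03 gate
    rng = np.random.default_rng(5)
    for _ in range(50):
        a = pd.DataFrame(rng.normal(0.3, 0.25, (1, 4)), index=["p"])
        b = pd.DataFrame(rng.normal(0.0, 0.25, (1, 4)), index=["p"])
        out = ps.ttest_de(a, b)
        fc, p = out.loc["p", "log2fc"], out.loc["p", "p"]
        if abs(fc) > 0.2 and 0.03 <= p < 0.08:
            assert not out.loc["p", "altered"]
            return
    pytest.fail("no case with |fc|>0.2 and borderline p found")


# -- imputation ---------------------------------------------------------------

def test_bpca_no_missing_identity():
    df = pd.DataFrame(np.random.default_rng(1).normal(size=(10, 4)))
    pd.testing.assert_frame_equal(ps.bpca_impute(df), df)


def test_bpca_rank1_completion_oracle():
    u = np.linspace(1, 20, 25)
    v = np.array([1.0, 0.8, 1.3, 0.6])
    X = np.outer(u, v)
    masked = X.copy()
    masked[4, 2] = np.nan
    filled = ps.bpca_impute(pd.DataFrame(masked))
    assert abs(filled.iloc[4, 2] - X[4, 2]) < 1e-6
    # observed values untouched
    obs = ~np.isnan(masked)
    np.testing.assert_array_equal(filled.to_numpy()[obs], X[obs])


def test_bpca_leaves_rows_with_two_missing():
    X = np.outer(np.arange(1, 11.0), [1.0, 1.1, 0.9, 1.2])
    X[3, 0] = np.nan
    X[3, 1] = np.nan
    out = ps.bpca_impute(pd.DataFrame(X))
    assert out.iloc[3, :2].isna().all()
    assert out.notna().iloc[3, 2:].all()


# -- labeling QC --------------------------------------------------------------

def test_labeling_qc_percentages():
    ev = pd.DataFrame({"tmt_sites": ["K,N-term"] * 98 + [""] * 2})
    under, over = ps.labeling_qc(ev)
    assert under == pytest.approx(2.0)
    assert over == pytest.approx(0.0)
    ev2 = pd.DataFrame({"tmt_sites": ["K"] * 49 + ["K,Y"]})
    under2, over2 = ps.labeling_qc(ev2)
    assert under2 == pytest.approx(0.0)
    assert over2 == pytest.approx(2.0)
    with pytest.raises(ps.ValidationError):
        ps.labeling_qc(pd.DataFrame({"tmt_sites": []}))


def test_labeling_qc_excludes_contaminants():
    ev = pd.DataFrame({"tmt_sites": ["", "K", "K", "K"],
                       "contaminant": [True, False, False, False]})
    under, over = ps.labeling_qc(ev)
    assert under == pytest.approx(0.0)


# -- strain summaries ---------------------------------------------------------

def test_summarize_strains_counts_and_coverage(screen_bundle):
    summary = screen_bundle["summary"].table
    de = screen_bundle["de"].table
    strain = summary.index[0]
    by_hand = int(de.query("strain_id == @strain")["altered"].sum())
    assert summary.loc[strain, "n_altered"] == by_hand
    assert (summary["n_altered"] <= summary["n_quantified"]).all()
    # desk-scale screens quantify ~800 proteins, below the screen's
    # 1250-protein repeat threshold: all flagged
    assert summary["low_coverage"].all()


def test_strain_with_no_small_q_has_zero_altered():
    table = pd.DataFrame(dict(
        protein_id=[f"p{i}" for i in range(5)],
        strain_id=["s"] * 5, sample_id=["x"] * 5,
        log2fc=0.0, z=0.0,
        p=[0.5, 0.9, 0.2, 0.8, 0.06],
        q=[0.5, 0.9, 0.5, 0.9, 0.3],
    ))
    table["altered"] = table["q"] < 0.05
    de = ps.DEResult(table=table)
    assert de.altered_counts()["s"] == 0


# -- screen-level statistical guarantees --------------------------------------

def test_null_screen_controls_false_positive_fraction():
    fracs = []
    for seed in (101, 102):
        cfg = ps.ScreenSimConfig(seed=seed, effect_fraction=0.0)
        m, manifest, _, _ = ps.generate_screen(cfg)
        normed, _ = ps.normalize_pipeline(m, manifest)
        ref = ps.build_wt_reference(normed, manifest)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            de = ps.ztest_de(normed, manifest, ref)
        fracs.append(de.table.groupby("strain_id")["altered"].mean().mean())
    assert np.mean(fracs) <= 0.05 + 0.01


def test_large_effects_detected_with_high_sensitivity(screen_bundle):
    cfg = screen_bundle["config"]
    truth = screen_bundle["truth"]
    de = screen_bundle["de"].table.set_index(["protein_id", "strain_id"])
    wt_sd = float(np.hypot(cfg.module_loading_sd, cfg.noise_sd))
    eff = truth.effects.stack()
    big = eff[np.abs(eff) >= 4 * wt_sd]
    tested = [i for i in big.index if i in de.index]
    sensitivity = de.loc[tested, "altered"].mean()
    assert sensitivity >= 0.9
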