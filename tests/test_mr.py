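import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy import stats

from mwaskit import mr, simulate
from mwaskit.datatypes import ValidationError


def _sumstats(rows):
    cols = ["variant_id", "chr", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pvalue", "n"]
    return pd.DataFrame(rows, columns=cols)


def _hset(bx, by, sy, sx=None):
    bx = np.asarray(bx, float)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(len(bx))],
            "bx": bx,
            "sx": sx if sx is not None else np.full(len(bx), 0.01),
            "by": by,
            "sy": sy,
            "eaf": 0.3,
            "palindromic": False,
            "f_statistic": (bx / 0.01) ** 2,
        }
    )


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

BASE_ROW = dict(chr="1", eaf=0.3, beta=0.2, se=0.02, pvalue=1e-10, n=10000)


def _row(vid, pos, ea="A", oa="G", **kw):
    d = {"variant_id": vid, "pos": pos, "effect_allele": ea, "other_allele": oa, **BASE_ROW}
    d.update(kw)
    return d


def test_strand_ambiguous_variants_removed():
    df = _sumstats([_row("rs1", 1e6, "A", "T"), _row("rs2", 30e6, "C", "G"),
                    _row("rs3", 60e6, "A", "G")])
    out = mr.select_instruments(df)
    assert out["variant_id"].tolist() == ["rs3"]


def test_maf_boundary():
    df = _sumstats([_row("rs1", 1e6, eaf=0.005), _row("rs2", 30e6, eaf=0.015),
                    _row("rs3", 60e6, eaf=0.995)])
    out = mr.select_instruments(df)
    assert out["variant_id"].tolist() == ["rs2"]  # eaf 0.995 -> maf 0.005 removed


def test_pvalue_threshold_strict():
    df = _sumstats([_row("rs1", 1e6, pvalue=5.0e-8), _row("rs2", 30e6, pvalue=4.9e-8)])
    out = mr.select_instruments(df)
    assert out["variant_id"].tolist() == ["rs2"]


def test_greedy_clump_keeps_smaller_p_of_correlated_pair():
    """Two significant SNPs 5,000 kb apart with r2 = 0.5: only the smaller-p
    one survives (hand-traced greedy clump)."""
    df = _sumstats([_row("rs1", 1_000_000, pvalue=1e-20),
                    _row("rs2", 6_000_000, pvalue=1e-10)])
    ld = {frozenset(("rs1", "rs2")): 0.5}
    out = mr.select_instruments(df, ld=ld)
    assert out["variant_id"].tolist() == ["rs1"]
    # with r2 below the threshold both survive
    ld2 = {frozenset(("rs1", "rs2")): 0.0005}
    out2 = mr.select_instruments(df, ld=ld2)
    assert set(out2["variant_id"]) == {"rs1", "rs2"}
    # without an LD map, distance-only clumping drops the weaker signal
    out3 = mr.select_instruments(df)
    assert out3["variant_id"].tolist() == ["rs1"]


def test_non_snv_variants_removed():
    df = _sumstats([_row("rs1", 1e6, "AT", "A"), _row("rs2", 30e6, "A", "A"),
                    _row("rs3", 60e6, "T", "C")])
    out = mr.select_instruments(df)
    assert out["variant_id"].tolist() == ["rs3"]


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def test_harmonize_flips_swapped_alleles():
    exp = _sumstats([_row("rs1", 1e6, "A", "G", beta=0.2)])
    out = _sumstats([_row("rs1", 1e6, "G", "A", beta=0.1, eaf=0.7)])
    h = mr.harmonize(exp, out)
    assert h["by"].iloc[0] == pytest.approx(-0.1)
    assert h["bx"].iloc[0] == pytest.approx(0.2)


def test_harmonize_identity_and_f_statistic():
    exp = _sumstats([_row("rs1", 1e6, "A", "G", beta=0.2, se=0.02)])
    out = _sumstats([_row("rs1", 1e6, "A", "G", beta=0.1)])
    h = mr.harmonize(exp, out)
    assert h["by"].iloc[0] == pytest.approx(0.1)
    assert h["f_statistic"].iloc[0] == pytest.approx((0.2 / 0.02) ** 2)


def test_harmonize_drops_allele_mismatch(caplog):
    exp = _sumstats([_row("rs1", 1e6, "A", "G"), _row("rs2", 30e6, "T", "C")])
    out = _sumstats([_row("rs1", 1e6, "A", "C"), _row("rs2", 30e6, "T", "C")])
    with caplog.at_level("WARNING", logger="mwaskit"):
        h = mr.harmonize(exp, out)
    assert h["variant_id"].tolist() == ["rs2"]
    assert any("mismatch" in r.message for r in caplog.records)


def test_harmonize_empty_intersection_errors():
    exp = _sumstats([_row("rs1", 1e6)])
    out = _sumstats([_row("rs9", 1e6)])
    with pytest.raises(ValidationError, match="shared"):
        mr.harmonize(exp, out)


def test_harmonization_involution_and_global_flip_invariance():
    """Harmonizing twice equals once; flipping both studies' allele order
    leaves all estimates unchanged."""
    exps, outcome, ld, _ = simulate.simulate_sumstats(
        simulate.MrSimConfig(n_metabolites=1, n_null_snps=0, seed=17))
    inst = mr.select_instruments(exps["M0000"], ld=ld)
    h1 = mr.harmonize(inst, outcome)
    # re-harmonize: express the harmonized set back as sumstats with exposure alleles
    out2 = outcome.copy()
    h2 = mr.harmonize(inst, out2)
    pd.testing.assert_frame_equal(h1, h2)
    # flip alleles and effect signs in both studies
    flip_exp = inst.copy()
    flip_exp[["effect_allele", "other_allele"]] = flip_exp[["other_allele", "effect_allele"]].to_numpy()
    flip_exp["beta"] = -flip_exp["beta"]
    flip_exp["eaf"] = 1 - flip_exp["eaf"]
    flip_out = outcome.copy()
    flip_out[["effect_allele", "other_allele"]] = flip_out[["other_allele", "effect_allele"]].to_numpy()
    flip_out["beta"] = -flip_out["beta"]
    flip_out["eaf"] = 1 - flip_out["eaf"]
    h3 = mr.harmonize(flip_exp, flip_out)
    assert mr.ivw(h3)["estimate"] == pytest.approx(mr.ivw(h1)["estimate"], rel=1e-12)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def test_single_snp_ivw_is_wald_ratio():
    h = _hset([0.2], [0.018], [0.004])
    res = mr.ivw(h, allow_single=True)
    assert res["estimate"] == pytest.approx(0.018 / 0.2)
    with pytest.raises(ValidationError, match="insufficient"):
        mr.ivw(h)


def test_identical_ratios_reproduce_common_value():
    bx = np.array([0.1, 0.2, 0.3])
    h = _hset(bx, 0.09 * bx, [0.004, 0.005, 0.006])
    res = mr.ivw(h)
    assert res["estimate"] == pytest.approx(0.09)
    assert res["odds_ratio"] == pytest.approx(np.exp(0.09))
    assert res["ci_low"] < res["odds_ratio"] < res["ci_high"]


def test_ivw_equals_origin_constrained_wls_oracle():
    """1,000 random instances against weighted least squares through the
    origin with weights 1/sy^2 (relative error < 1e-10)."""
    rng = np.random.default_rng(19)
    for _ in range(1000):
        k = int(rng.integers(2, 15))
        bx = rng.normal(0.2, 0.1, k) + 0.05
        by = rng.normal(0.0, 0.05, k)
        sy = rng.uniform(0.002, 0.05, k)
        h = _hset(bx, by, sy)
        est = mr.ivw(h)["estimate"]
        w = 1.0 / sy**2
        oracle = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert abs(est - oracle) <= 1e-10 * max(1.0, abs(oracle))


def test_ivw_fixed_se_matches_wls_and_inflation_kicks_in():
    rng = np.random.default_rng(20)
    bx = rng.normal(0.3, 0.05, 8)
    sy = np.full(8, 0.01)
    by_hom = 0.1 * bx
    res_hom = mr.ivw(_hset(bx, by_hom, sy))
    assert res_hom["inflation"] == 1.0
    by_het = 0.1 * bx + rng.normal(0, 0.05, 8)
    res_het = mr.ivw(_hset(bx, by_het, sy))
    assert res_het["inflation"] > 1.0
    assert res_het["se"] > res_het["se_fixed"]


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def test_weighted_median_equal_ratios():
    bx = np.array([0.1, 0.2, 0.3])
    h = _hset(bx, 0.07 * bx, [4e-4, 5e-4, 6e-4], sx=np.full(3, 1e-6))
    res = mr.weighted_median(h, n_boot=200, seed=1)
    assert res["estimate"] == pytest.approx(0.07, abs=1e-10)
    assert res["se"] < 0.005  # bootstrap se shrinks with the outcome noise


def test_weighted_median_resists_low_weight_outlier():
    """theta = (0.1, 0.1, 5.0) with dominant weight on the first two: the
    weighted 50% quantile stays near 0.1 (hand-computed interpolation)."""
    bx = np.array([0.5, 0.5, 0.01])
    by = np.array([0.05, 0.05, 0.05])  # ratios 0.1, 0.1, 5.0
    sy = np.array([0.01, 0.01, 0.01])
    h = _hset(bx, by, sy)
    res = mr.weighted_median(h, n_boot=100, seed=2)
    # hand computation: weights prop to (0.5/0.01)^2, (0.5/0.01)^2, 1 ->
    # cumulative midpoint of the second ratio straddles 0.5 -> estimate 0.1
    assert res["estimate"] == pytest.approx(0.1, abs=1e-6)


def test_weighted_median_needs_three_snps():
    with pytest.raises(ValidationError):
        mr.weighted_median(_hset([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))


@given(st.integers(0, 1000))
def test_weighted_median_within_ratio_range(seed):
    rng = np.random.default_rng(seed)
    k = int(rng.integers(3, 12))
    bx = rng.normal(0.3, 0.1, k) + 0.05
    by = rng.normal(0.02, 0.05, k)
    sy = rng.uniform(0.005, 0.05, k)
    est = mr.weighted_median(_hset(bx, by, sy), n_boot=10, seed=seed)["estimate"]
    theta = by / bx
    assert theta.min() - 1e-12 <= est <= theta.max() + 1e-12


# ---------------------------------------------------------------------------
# Egger, Q, global outlier test
# ---------------------------------------------------------------------------

def test_egger_slope_matches_wls_oracle():
    rng = np.random.default_rng(23)
    for _ in range(50):
        k = int(rng.integers(3, 15))
        bx = np.abs(rng.normal(0.3, 0.1, k)) + 0.02
        by = 0.01 + 0.1 * bx + rng.normal(0, 0.02, k)
        sy = rng.uniform(0.005, 0.05, k)
        res = mr.mr_egger(_hset(bx, by, sy))
        X = sm.add_constant(bx)
        ref = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        assert res["estimate"] == pytest.approx(ref.params[1], rel=1e-8)
        assert res["intercept"] == pytest.approx(ref.params[0], rel=1e-8, abs=1e-12)


def test_egger_orientation_flip_makes_bx_nonnegative():
    bx = np.array([0.3, -0.25, 0.2, -0.4])
    by = 0.1 * bx + 0.02 * np.sign(bx)  # directional in the oriented frame
    res = mr.mr_egger(_hset(bx, by, np.full(4, 0.01)))
    flipped = mr.mr_egger(_hset(np.abs(bx), 0.1 * np.abs(bx) + 0.02, np.full(4, 0.01)))
    assert res["estimate"] == pytest.approx(flipped["estimate"], rel=1e-10)
    assert res["intercept"] == pytest.approx(flipped["intercept"], rel=1e-10)


def test_egger_zero_pleiotropy_intercept_near_zero():
    """Without pleiotropy the intercept is ~0 within its own 2-SE band in each
    replicate (finite between-instrument spread in |bx| leaves a small
    deterministic NOME term well inside the per-fit SE, so the 5% intercept
    test rejects at roughly its nominal rate)."""
    ints, ses, rejected = [], [], 0
    n_rep = 50
    for rep in range(n_rep):
        cfg = simulate.MrSimConfig(n_metabolites=1, n_causal=1, theta=0.09,
                                   n_null_snps=0, palindromic_frac=0.0, seed=400 + rep)
        exps, outcome, ld, _ = simulate.simulate_sumstats(cfg)
        h = mr.harmonize(mr.select_instruments(exps["M0000"], ld=ld), outcome)
        res = mr.mr_egger(h)
        ints.append(res["intercept"])
        ses.append(res["intercept_se"])
        rejected += res["intercept_pvalue"] < 0.05
    assert abs(np.mean(ints)) < np.mean(ses)
    assert rejected / n_rep <= 0.15


def test_cochran_q_zero_on_identical_ratios_and_permutation_invariant():
    bx = np.array([0.1, 0.2, 0.3, 0.15])
    h = _hset(bx, 0.05 * bx, [0.004, 0.005, 0.006, 0.003])
    res = mr.cochran_q(h)
    assert res["Q"] == pytest.approx(0.0, abs=1e-20)
    assert res["pvalue"] == pytest.approx(1.0)
    rng = np.random.default_rng(25)
    by = 0.05 * bx + rng.normal(0, 0.01, 4)
    h2 = _hset(bx, by, [0.004, 0.005, 0.006, 0.003])
    q1 = mr.cochran_q(h2)["Q"]
    perm = np.array([2, 0, 3, 1])
    h3 = h2.iloc[perm].reset_index(drop=True)
    assert mr.cochran_q(h3)["Q"] == pytest.approx(q1, rel=1e-12)


def test_homogeneous_simulation_q_over_df_near_one():
    ratios = []
    for rep in range(100):
        cfg = simulate.MrSimConfig(n_metabolites=1, n_causal=1, theta=0.09,
                                   n_null_snps=0, palindromic_frac=0.0, seed=500 + rep)
        exps, outcome, ld, _ = simulate.simulate_sumstats(cfg)
        h = mr.harmonize(mr.select_instruments(exps["M0000"], ld=ld), outcome)
        q = mr.cochran_q(h)
        ratios.append(q["Q"] / q["df"])
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


def test_presso_p_bounds_and_outlier_detection():
    rng = np.random.default_rng(26)
    bx = np.abs(rng.normal(0.3, 0.05, 12))
    sy = np.full(12, 0.01)
    by = 0.1 * bx + rng.normal(0, sy)
    res = mr.presso_global(_hset(bx, by, sy), n_sim=500, seed=0)
    assert 1 / 501 <= res["pvalue"] <= 1.0
    by_out = by.copy()
    by_out[0] += 10 * sy[0]
    res_out = mr.presso_global(_hset(bx, by_out, sy), n_sim=500, seed=0)
    assert res_out["pvalue"] < 0.05


def test_presso_skips_small_sets(caplog):
    with caplog.at_level("WARNING", logger="mwaskit"):
        res = mr.presso_global(_hset([0.1, 0.2, 0.3], [0.01, 0.02, 0.03], [0.01] * 3))
    assert np.isnan(res["pvalue"])


def test_loo_and_single_snp_counts_and_shift():
    """3-SNP fixture: removing the dominant-weight SNP moves the leave-one-out
    estimate toward the remaining SNPs' common ratio (hand-computed)."""
    bx = np.array([1.0, 0.2, 0.2])
    by = np.array([0.3, 0.02, 0.02])  # dominant ratio 0.3, others 0.1
    sy = np.array([0.01, 0.01, 0.01])
    h = _hset(bx, by, sy)
    single, loo = mr.loo_and_single_snp(h)
    assert len(single) == 3 and len(loo) == 3
    assert single["estimate"].tolist() == pytest.approx([0.3, 0.1, 0.1])
    full = mr.ivw(h)["estimate"]
    without_dominant = loo.set_index("left_out").loc["rs0", "estimate"]
    assert without_dominant == pytest.approx(0.1, abs=1e-12)
    assert abs(without_dominant - 0.1) < abs(full - 0.1)
    # homogeneous set: every leave-one-out estimate within every other's CI
    hb = _hset(np.array([0.2, 0.3, 0.4]), 0.1 * np.array([0.2, 0.3, 0.4]), [0.01] * 3)
    _, loo_h = mr.loo_and_single_snp(hb)
    ests = loo_h["estimate"]
    assert ests.max() - ests.min() < 2 * loo_h["se"].min()


def test_single_snp_excludes_zero_bx(caplog):
    h = _hset([0.0, 0.2, 0.3], [0.01, 0.02, 0.03], [0.01] * 3)
    with caplog.at_level("WARNING", logger="mwaskit"):
        single, _ = mr.loo_and_single_snp(h)
    assert len(single) == 2


# ---------------------------------------------------------------------------
# pipeline gate
# ---------------------------------------------------------------------------

def test_pipeline_excludes_single_instrument_metabolite():
    exps, outcome, ld, _ = simulate.simulate_sumstats(
        simulate.MrSimConfig(n_metabolites=2, seed=27))
    # cripple one exposure: keep only its single most significant instrument
    weak = exps["M0001"].sort_values("pvalue").head(1).reset_index(drop=True)
    results, details, skipped = mr.mr_pipeline({"M0000": exps["M0000"], "M0001": weak},
                                               outcome, ld)
    assert skipped["metabolite_id"].tolist() == ["M0001"]
    assert "instrument" in skipped["reason"].iloc[0]
    assert results["metabolite_id"].tolist() == ["M0000"]
    assert (results["min_f_statistic"] > 10).all()


def test_pipeline_empty_when_no_metabolite_passes(caplog):
    exps, outcome, ld, _ = simulate.simulate_sumstats(
        simulate.MrSimConfig(n_metabolites=1, seed=28))
    weak = exps["M0000"].sort_values("pvalue").head(1).reset_index(drop=True)
    with caplog.at_level("WARNING", logger="mwaskit"):
        results, details, skipped = mr.mr_pipeline({"M0000": weak}, outcome, ld)
    assert results.empty
    assert len(skipped) == 1
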