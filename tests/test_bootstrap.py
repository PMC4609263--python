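import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wincurse.bootstrap import (
    GWBootstrapCorrector,
    correlation_adjust,
    draw_replicate,
    gw_decomposition_diagnostic,
    maf_rescale_factor,
    ss_bias_reduce,
)
from wincurse.data import SelectionRule
from wincurse.scan import CoxSNPScan


# ---------------------------------------------------------------------------
# resampling primitives
# ---------------------------------------------------------------------------


def test_draw_replicate_is_a_partition():
    within, out = draw_replicate(100, seed=4)
    assert len(within) == 100
    assert set(within) | set(out) == set(range(100))
    assert set(within) & set(out) == set()


def test_draw_replicate_deterministic():
    a = draw_replicate(50, seed=9)
    b = draw_replicate(50, seed=9)
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])


def test_out_fraction_approaches_e_inverse():
    """|out|/n -> (1-1/n)^n ~ e^-1 over replicates."""
    n, reps = 1000, 200
    fracs = [len(draw_replicate(n, seed=100 + i)[1]) / n for i in range(reps)]
    mc_se = np.sqrt(np.exp(-1) * (1 - np.exp(-1)) / n) / np.sqrt(reps)
    assert abs(np.mean(fracs) - np.exp(-1)) < 3 * mc_se + 2e-4


@pytest.mark.parametrize(
    "p_i, p, expected",
    [
        (0.3, 0.3, 1.0),
        (0.5, 0.1, np.sqrt(0.5 / 0.18)),  # ~1.6667
    ],
)
def test_maf_rescale_examples(p_i, p, expected):
    assert maf_rescale_factor(p_i, p) == pytest.approx(expected, rel=1e-12)


@given(
    st.floats(0.01, 0.5, allow_nan=False), st.floats(0.01, 0.5, allow_nan=False)
)
def test_maf_rescale_reciprocal_symmetry(p_i, p):
    assert maf_rescale_factor(p_i, p) * maf_rescale_factor(p, p_i) == pytest.approx(
        1.0, rel=1e-9
    )


def test_maf_rescale_rejects_monomorphic():
    with pytest.raises(ValueError):
        maf_rescale_factor(0.0, 0.2)


@pytest.mark.parametrize(
    "bo, bw, bn, ratio, expected",
    [
        (0.30, 0.40, 0.20, 0.0, 0.30),  # no-adjustment limit
        (0.30, 0.25, 0.25, -0.7, 0.30),  # zero deviation
        (0.20, 0.35, 0.25, -0.4, 0.24),  # direct arithmetic
    ],
)
def test_correlation_adjust(bo, bw, bn, ratio, expected):
    assert correlation_adjust(bo, bw, bn, ratio) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# genome-wide corrector
# ---------------------------------------------------------------------------


def oracle_from_records(records: pd.DataFrame, estimates: pd.DataFrame) -> dict:
    """Straight-line reimplementation of the bias-reduction arithmetic from
    the persisted replicate records, independent of the package internals."""
    out = {}
    for _, row in estimates.iterrows():
        k = row["rank"]
        rk = records[(records["rank"] == k) & records["out_converged"]]
        bw = rk["beta_within"].to_numpy()
        bo = rk["beta_out"].to_numpy()
        bn_i = rk["beta_orig_of_selected"].to_numpy()
        if len(bw) >= 2 and np.var(bw, ddof=1) > 0:
            ratio = np.cov(bw, bo, ddof=1)[0, 1] / np.var(bw, ddof=1)
        else:
            ratio = 0.0
        bo_star = bo - ratio * (bw - bn_i)
        p_i = rk["maf_replicate"].to_numpy()
        p_k = row["maf"]
        fac = np.sqrt(2 * p_i * (1 - p_i)) / np.sqrt(2 * p_k * (1 - p_k))
        bias = np.mean((bw - bo_star) * fac)
        out[row["snp_id"]] = max(row["beta_naive"] - bias, 0.0)
    return out


@pytest.fixture(scope="module")
def fitted_corrector(small_dataset):
    g, ph = small_dataset
    corr = GWBootstrapCorrector(
        alpha=0.05, B=25, compute_ss=True, random_state=31
    )
    return corr.fit(g, ph)


def test_gw_oracle_equivalence_from_records(fitted_corrector):
    """Recomputing the correction from persisted records reproduces beta_gw
    to 1e-12."""
    corr = fitted_corrector
    assert len(corr.estimates_) >= 1
    oracle = oracle_from_records(corr.records_, corr.estimates_)
    for _, row in corr.estimates_.iterrows():
        assert row["beta_gw"] == pytest.approx(oracle[row["snp_id"]], abs=1e-12)


def test_records_schema_and_accounting(fitted_corrector):
    corr = fitted_corrector
    rec = corr.records_
    assert set(rec["replicate"]) <= set(range(1, 26))
    assert (rec["rank"] >= 1).all()
    assert (corr.estimates_["B_used"] <= 25).all()
    # B(k) counts replicates with >= k selected SNPs (and usable out fits)
    for _, row in corr.estimates_.iterrows():
        k = row["rank"]
        expected = int(
            ((rec["rank"] == k) & rec["out_converged"]).sum()
        )
        assert row["B_used"] == expected


def test_gw_truncation_at_null(fitted_corrector):
    est = fitted_corrector.estimates_
    assert (est["beta_gw"].dropna() >= 0).all()
    raw = est["beta_naive"] - est["bias_estimate"]
    np.testing.assert_array_equal((raw < 0).to_numpy(), est["truncated"].to_numpy())


def test_gw_deterministic_under_seed(small_dataset):
    g, ph = small_dataset
    a = GWBootstrapCorrector(alpha=0.05, B=10, random_state=5).fit(g, ph)
    b = GWBootstrapCorrector(alpha=0.05, B=10, random_state=5).fit(g, ph)
    pd.testing.assert_frame_equal(a.estimates_, b.estimates_)
    pd.testing.assert_frame_equal(a.records_, b.records_)


def _inject(corr, records, res, sel_order):
    corr.records_ = records
    return corr._estimates_from_records(res, sel_order)


def _fake_scan_result(beta=0.30, maf=0.25):
    from wincurse.data import AssocScanResult, SelectionRule

    return AssocScanResult(
        snp_ids=np.array(["rsX"], dtype=object),
        beta_naive=np.array([beta]),
        se=np.array([0.1]),
        p_value=np.array([1e-4]),
        maf=np.array([maf]),
        recoded=np.array([False]),
        converged=np.array([True]),
        selected=np.array([True]),
        rank=np.array([1.0]),
        n_events=50,
        rule=SelectionRule(alpha=0.01),
    )


def _records_frame(bw, bo, bn, maf):
    B = len(bw)
    return pd.DataFrame(
        {
            "replicate": np.arange(1, B + 1),
            "rank": np.ones(B, dtype=int),
            "snp_id": ["rsX"] * B,
            "beta_within": bw,
            "beta_out": bo,
            "var_within": np.full(B, 0.01),
            "var_out": np.full(B, 0.02),
            "maf_replicate": np.full(B, maf),
            "maf_within": np.full(B, maf),
            "beta_orig_of_selected": bn,
            "out_converged": [True] * B,
        }
    )


def test_no_selection_pressure_gives_zero_bias():
    """beta_D = beta_E with matching MAFs in every replicate: the corrected
    estimate equals the naive one."""
    res = _fake_scan_result(beta=0.30, maf=0.25)
    bw = np.array([0.28, 0.33, 0.31, 0.29])
    recs = _records_frame(bw, bw.copy(), np.full(4, 0.30), maf=0.25)
    corr = GWBootstrapCorrector(alpha=0.01, B=4, adjust="none")
    est = _inject(corr, recs, res, np.array([0]))
    assert est.loc[0, "beta_gw"] == pytest.approx(0.30, abs=1e-12)
    assert not est.loc[0, "truncated"]


def test_truncation_when_bias_exceeds_naive():
    """Naive 0.10 with mean rescaled difference 0.30 -> corrected 0, flagged."""
    res = _fake_scan_result(beta=0.10, maf=0.25)
    bw = np.array([0.45, 0.45, 0.45, 0.45])
    bo = np.array([0.15, 0.15, 0.15, 0.15])
    recs = _records_frame(bw, bo, np.full(4, 0.10), maf=0.25)
    corr = GWBootstrapCorrector(alpha=0.01, B=4, adjust="none")
    est = _inject(corr, recs, res, np.array([0]))
    assert est.loc[0, "bias_estimate"] == pytest.approx(0.30, abs=1e-12)
    assert est.loc[0, "beta_gw"] == 0.0
    assert bool(est.loc[0, "truncated"])


def test_empty_rank_reports_undefined():
    res = _fake_scan_result()
    recs = _records_frame(np.array([0.3]), np.array([0.2]), np.array([0.3]), 0.25)
    recs["out_converged"] = [False]
    corr = GWBootstrapCorrector(alpha=0.01, B=1)
    est = _inject(corr, recs, res, np.array([0]))
    assert est.loc[0, "B_used"] == 0
    assert np.isnan(est.loc[0, "beta_gw"])


# ---------------------------------------------------------------------------
# single-SNP bootstrap
# ---------------------------------------------------------------------------


def test_ss_bootstrap_strong_snp(strong_snp_dataset):
    """Overwhelming effect: every replicate qualifies and the SS estimate
    stays close to (and never flips sign from) the naive estimate."""
    g, ph = strong_snp_dataset
    scan = CoxSNPScan(alpha=0.01).fit(g, ph)
    snp = scan.result_.snp_ids[scan.result_.selected_order()[0]]
    est, n_used = ss_bias_reduce(
        snp, g, ph, SelectionRule(alpha=0.01), B=40, seed=11, scan=scan
    )
    assert n_used == 40
    naive = scan.result_.beta_naive[scan.result_.index_of(snp)]
    assert 0 <= est <= naive * 1.1
    assert est == pytest.approx(naive, abs=0.15)


def test_ss_bootstrap_no_qualifying_replicates(small_dataset):
    g, ph = small_dataset
    scan = CoxSNPScan(alpha=0.9).fit(g, ph)
    res = scan.result_
    # pick a selected SNP that is far from significance at a tiny threshold
    order = res.selected_order()
    weak = res.snp_ids[order[-1]]
    est, n_used = ss_bias_reduce(
        weak, g, ph, SelectionRule(alpha=1e-12), B=10, seed=3, scan=scan
    )
    assert n_used == 0 and np.isnan(est)


def test_ss_requires_selected_snp(small_dataset):
    g, ph = small_dataset
    scan = CoxSNPScan(alpha=1e-300).fit(g, ph)
    with pytest.raises(ValueError, match="not selected"):
        ss_bias_reduce(
            scan.result_.snp_ids[0], g, ph, SelectionRule(alpha=1e-300), scan=scan
        )


# ---------------------------------------------------------------------------
# decomposition diagnostic
# ---------------------------------------------------------------------------


def test_decomposition_all_concordant(strong_snp_dataset):
    g, ph = strong_snp_dataset
    corr = GWBootstrapCorrector(alpha=0.01, B=15, random_state=2).fit(g, ph)
    top = corr.estimates_.loc[0, "snp_id"]
    dec = gw_decomposition_diagnostic(corr.records_, top)
    assert dec.B_Cstar == 0
    assert dec.delta_GW == pytest.approx(dec.delta_C)


def test_decomposition_recombination_identity():
    """(B_C/B) Delta_C + (B_C*/B) Delta_C* equals the overall rank-1 mean
    difference when no rescaling/adjustment is involved."""
    rng = np.random.default_rng(8)
    B = 30
    recs = _records_frame(
        rng.normal(0.3, 0.05, B), rng.normal(0.2, 0.05, B), np.full(B, 0.3), 0.25
    )
    recs.loc[:9, "snp_id"] = "rsOther"
    dec = gw_decomposition_diagnostic(recs, "rsX")
    assert dec.B_C + dec.B_Cstar == B
    overall = (recs["beta_within"] - recs["beta_out"]).mean()
    assert dec.delta_GW == pytest.approx(overall, abs=1e-12)


def test_decomposition_null_heavy_discordant_positive():
    """Replicates that top-rank a *different* (null) SNP are there because its
    estimate was exaggerated: Delta_C* > 0 on average."""
    g, ph = _null_heavy_dataset()
    corr = GWBootstrapCorrector(alpha=0.15, B=40, random_state=13).fit(g, ph)
    top = corr.estimates_.loc[0, "snp_id"]
    dec = gw_decomposition_diagnostic(corr.records_, top)
    assert dec.B_Cstar >= 5
    assert dec.delta_Cstar > 0


def _null_heavy_dataset():
    """Many null SNPs and one weak true SNP: replicate top ranks wander."""
    from wincurse.simulate import BaselineHazard, SimSpec, assemble_dataset

    spec = SimSpec(
        n_individuals=250,
        snp_spec=[(0.3, f"g{j}") for j in range(20)],
        true_snps={0: 0.25},
        strata={"_all": BaselineHazard.exponential(rate=0.08, last_time=15.0)},
    )
    return assemble_dataset(spec, seed=515)


def test_ss_from_records_matches_independent_arithmetic():
    """The SS estimate derived from shared replicate records equals a
    straight-line recomputation of Delta_SS with adjustment and MAF factor."""
    from wincurse.bootstrap import _ss_from_records

    rng = np.random.default_rng(21)
    B = 50
    bw = rng.normal(0.35, 0.06, B)
    bo = rng.normal(0.22, 0.08, B)
    maf_w = rng.uniform(0.22, 0.28, B)
    recs = _records_frame(bw, bo, np.full(B, 0.30), maf=0.25)
    recs["maf_within"] = maf_w
    est, n_used = _ss_from_records(recs, "rsX", beta_orig=0.30, maf_orig=0.25)
    assert n_used == B
    ratio = np.cov(bw, bo, ddof=1)[0, 1] / np.var(bw, ddof=1)
    bo_star = bo - ratio * (bw - 0.30)
    fac = np.sqrt(2 * maf_w * (1 - maf_w)) / np.sqrt(2 * 0.25 * 0.75)
    expected = max(0.30 - np.mean((bw - bo_star) * fac), 0.0)
    assert est == pytest.approx(expected, abs=1e-12)


def test_hybrid_adjustment_variant_runs(small_dataset):
    g, ph = small_dataset
    corr = GWBootstrapCorrector(
        alpha=0.05, B=10, adjust="hybrid", random_state=3
    ).fit(g, ph)
    est = corr.estimates_["beta_gw"].dropna()
    assert len(est) >= 1 and (est >= 0).all()


def test_functional_wrappers_match_estimators(small_dataset):
    from wincurse.bootstrap import gw_bias_reduce

    g, ph = small_dataset
    df = gw_bias_reduce(g, ph, SelectionRule(alpha=0.05), B=8, seed=5)
    est = GWBootstrapCorrector(alpha=0.05, B=8, random_state=5).fit(g, ph).estimates_
    pd.testing.assert_frame_equal(df, est)
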