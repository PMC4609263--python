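import numpy as np
import pytest
from scipy import stats

from wincurse.data import SurvivalPhenotype
from wincurse.simulate import (
    BaselineHazard,
    SimSpec,
    application_design_spec,
    assemble_dataset,
    bender_generate,
    estimate_baseline,
    expand_genotypes,
    reduced_design_spec,
    synth_genotypes,
)
from wincurse.study import ld_r2


# ---------------------------------------------------------------------------
# genotype generation
# ---------------------------------------------------------------------------


def test_synth_maf_concentration():
    g = synth_genotypes([(0.5, "g1")], n=10_000, seed=1)
    assert abs(g.maf()[0] - 0.5) < 0.015


def test_synth_rejects_invalid_maf():
    with pytest.raises(ValueError):
        synth_genotypes([(0.0, "g1")], n=10, seed=1)


def test_synth_deterministic():
    a = synth_genotypes([(0.2, "g1"), (0.4, "g2")], n=50, seed=3)
    b = synth_genotypes([(0.2, "g1"), (0.4, "g2")], n=50, seed=3)
    np.testing.assert_array_equal(a.dosages, b.dosages)


def test_synth_within_block_ld():
    spec = [(0.3, "g1"), (0.3, "g1"), (0.3, "g2")]
    g = synth_genotypes(spec, n=5_000, seed=5, ld_rho=0.8)
    within = ld_r2(g.dosages[:, 0], g.dosages[:, 1])
    across = ld_r2(g.dosages[:, 0], g.dosages[:, 2])
    assert within > 0.2
    assert across < 0.05
    # marginal MAF preserved under the LD construction
    assert abs(g.maf()[0] - 0.3) < 0.02


# ---------------------------------------------------------------------------
# two-donor expansion
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def source_panel():
    spec = [(m, f"gene{j // 4}") for j, m in enumerate(
        np.linspace(0.08, 0.45, 24)
    )]
    return synth_genotypes(spec, n=800, seed=42)


def test_expansion_preserves_maf(source_panel):
    """Per-SNP MAF is preserved up to donor-resampling noise (~0.4 pp SD at
    a 4x expansion); on average the drift is well under half a point."""
    big = expand_genotypes(source_panel, target_n=3200, seed=9)
    assert big.n_individuals == 3200
    np.testing.assert_array_equal(big.dosages[:800], source_panel.dosages)
    drift = np.abs(big.maf() - source_panel.maf())
    assert drift.mean() < 0.005
    assert drift.max() < 0.015


def test_expansion_identity_when_target_equals_source(source_panel):
    same = expand_genotypes(source_panel, target_n=800, seed=9)
    np.testing.assert_array_equal(same.dosages, source_panel.dosages)


def test_expansion_block_integrity(source_panel):
    """Within any gene block, a new individual's genotype vector is copied
    verbatim from a single source individual."""
    big, d1, d2 = expand_genotypes(
        source_panel, target_n=1000, seed=9, return_donors=True
    )
    new = big.dosages[800:]
    for block in set(source_panel.gene_block):
        cols = np.nonzero(source_panel.gene_block == block)[0]
        src = source_panel.dosages[:, cols]
        for i in range(new.shape[0]):
            row = new[i, cols]
            assert (
                np.array_equal(row, src[d1[i]]) or np.array_equal(row, src[d2[i]])
            )


# ---------------------------------------------------------------------------
# baseline hazards and event-time generation
# ---------------------------------------------------------------------------


def test_nelson_aalen_hand_computed():
    """Events at t=1,2 with risk sets of 2 and 1: H(1)=0.5, H(2)=1.5."""
    ph = SurvivalPhenotype(time=np.array([1.0, 2.0]), event=np.array([1, 1]))
    hz = estimate_baseline(ph)["_all"]
    np.testing.assert_allclose(hz.times, [1.0, 2.0])
    np.testing.assert_allclose(hz.cumhaz, [0.5, 1.5])
    assert hz.last_time == 2.0


def test_nelson_aalen_recovers_exponential_rate():
    rng = np.random.default_rng(3)
    lam = 0.25
    t = -np.log(rng.random(20_000)) / lam
    ph = SurvivalPhenotype(time=t, event=np.ones_like(t, dtype=bool))
    hz = estimate_baseline(ph)["_all"]
    mid = np.searchsorted(hz.times, np.quantile(t, 0.5))
    assert hz.cumhaz[mid] == pytest.approx(lam * hz.times[mid], rel=0.05)


def test_all_censored_stratum_errors():
    ph = SurvivalPhenotype(time=np.array([1.0, 2.0]), event=np.array([0, 0]))
    with pytest.raises(ValueError, match="no events"):
        estimate_baseline(ph)


def test_bender_exponential_is_exponential():
    """Parametric H0(t) = lambda t with eta = 0: T ~ Exponential(lambda)."""
    hz = BaselineHazard.exponential(rate=0.2, last_time=1e9)
    t, e = bender_generate(np.zeros(10_000), hz, seed=11)
    assert e.all()
    ks = stats.kstest(t, "expon", args=(0, 1 / 0.2))
    assert ks.pvalue > 0.01


def test_bender_step_boundary_first_step():
    """h* below the first step lands on the first step time."""
    hz = BaselineHazard(
        stratum="s", times=np.array([2.0, 5.0]), cumhaz=np.array([0.3, 0.9]),
        last_time=6.0,
    )
    t, e = hz.invert(np.array([1e-9, 0.3, 0.31, 1.0]))
    np.testing.assert_allclose(t, [2.0, 2.0, 5.0, 6.0])
    np.testing.assert_array_equal(e, [True, True, True, False])


def test_bender_eta_cap_no_overflow():
    hz = BaselineHazard.exponential(rate=0.1, last_time=50.0)
    t, e = bender_generate(np.array([1e6, -1e6]), hz, seed=2)
    assert np.isfinite(t).all()
    assert not e[1]  # enormous negative eta -> censored


def test_censoring_monotone_in_horizon():
    spec_long = reduced_design_spec(n=600, n_snps=20)
    short = {
        k: BaselineHazard.exponential(rate=v.rate, last_time=6.0, stratum=k)
        for k, v in spec_long.strata.items()
    }
    spec_short = SimSpec(
        n_individuals=600,
        snp_spec=spec_long.snp_spec,
        true_snps=spec_long.true_snps,
        covariate_betas=spec_long.covariate_betas,
        strata=short,
    )
    _, ph_long = assemble_dataset(spec_long, 77)
    _, ph_short = assemble_dataset(spec_short, 77)
    assert ph_short.n_events < ph_long.n_events


def test_assemble_deterministic():
    spec = reduced_design_spec(n=200, n_snps=15)
    g1, p1 = assemble_dataset(spec, 5)
    g2, p2 = assemble_dataset(spec, 5)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    np.testing.assert_allclose(p1.time, p2.time)
    np.testing.assert_array_equal(p1.event, p2.event)


def test_estimated_baseline_roundtrip_generates_similar_censoring():
    """Nelson-Aalen baseline estimated from one dataset can drive generation."""
    spec = reduced_design_spec(n=500, n_snps=15)
    _, ph = assemble_dataset(spec, 31)
    hazards = estimate_baseline(ph)
    eta = np.zeros(400)
    lab = ph.strata_labels()[0]
    t, e = bender_generate(eta, hazards[str(lab)], seed=8)
    assert t.max() <= hazards[str(lab)].last_time + 1e-9
    assert 0 < e.mean() < 1


def test_design_profiles_validate():
    red = reduced_design_spec()
    app = application_design_spec()
    assert red.n_snps == 300 and app.n_snps == 1213
    assert len(app.true_snps) == 19
    # true-SNP MAFs of the application profile match the generating table
    mafs = [app.snp_spec[j][0] for j in sorted(app.true_snps)[:15]]
    assert mafs[0] == pytest.approx(0.103)
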