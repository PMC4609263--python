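import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from wincurse.data import GenotypeMatrix, SurvivalPhenotype
from wincurse.simulate import BaselineHazard, SimSpec, assemble_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_exponential_spec(
    n=300, mafs=(0.3, 0.2, 0.4), true_betas=(0.8, 0.0, 0.0), rate=0.08, horizon=15.0
):
    """Small single-stratum design with an exponential baseline, no covariates."""
    snp_spec = [(m, f"gene{j+1}") for j, m in enumerate(mafs)]
    true = {j: b for j, b in enumerate(true_betas) if b != 0.0}
    return SimSpec(
        n_individuals=n,
        snp_spec=snp_spec,
        true_snps=true,
        covariate_betas={},
        strata={"_all": BaselineHazard.exponential(rate=rate, last_time=horizon)},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """n=300, 3 SNPs, one strong true effect; used across scan/bootstrap tests."""
    spec = make_exponential_spec()
    return assemble_dataset(spec, seed=2024)


@pytest.fixture(scope="session")
def strong_snp_dataset():
    """One overwhelming effect so every bootstrap replicate selects it first."""
    spec = make_exponential_spec(
        n=400, mafs=(0.4, 0.3), true_betas=(1.6, 0.0), rate=0.05
    )
    return assemble_dataset(spec, seed=7)


@pytest.fixture
def tiny_genotypes():
    return GenotypeMatrix(
        dosages=np.array([[0.0, 1.0], [2.0, 1.0]]),
        snp_ids=np.array(["rs1", "rs2"]),
        gene_block=np.array(["g1", "g1"]),
    )


@pytest.fixture
def eight_subject_phenotype():
    return SurvivalPhenotype(
        time=np.arange(1.0, 9.0), event=np.ones(8, dtype=bool)
    )
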