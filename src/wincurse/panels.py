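"""Published summary statistics from the DCCT/EDIC nephropathy candidate-gene scan.

The DCCT/EDIC Genetics Study analysed time to severe nephropathy in 1,361
white probands with type 1 diabetes (115 events) across 1,213 SNPs with
MAF >= 5% in 201 candidate genes. These tables carry the reported summary
statistics for the 15 SNPs significant at the 1% level (naive and genome-wide
bootstrap logHR estimates) and the generating model used in the simulation
evaluation (per-SNP MAF, data-generated logHR, and risk-allele orientation).
They serve as worked-example inputs for the power calculator and risk-score
operations, and as the default true-SNP panel of the application-scale
simulator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TOP_SNPS",
    "GENERATING_MODEL_COMMON",
    "LOW_FREQUENCY_TRUE_SNPS",
    "N_INDIVIDUALS",
    "N_EVENTS",
    "ALPHA_APPLICATION",
]

N_INDIVIDUALS = 1361
N_EVENTS = 115
ALPHA_APPLICATION = 0.01

# Top 15 SNPs of the application scan (threshold p < 0.01): gene, rs id,
# MAF (fraction), Wald p, naive |logHR|, GW bootstrap estimate, and whether
# the minor allele is the risk allele (otherwise the major allele is).
TOP_SNPS = pd.DataFrame(
    [
        ("LIPC", "rs1968685", 0.483, 2.22e-4, 0.51, 0.29, False),
        ("LIPC", "rs7178362", 0.137, 2.36e-4, 0.56, 0.22, True),
        ("FLT1", "rs7999615", 0.062, 6.13e-4, 0.75, 0.27, False),
        ("SOD1", "rs17880135", 0.056, 8.18e-4, 0.69, 0.17, True),
        ("VDR", "rs2254210", 0.363, 2.61e-3, 0.39, 0.16, False),
        ("PRKCB1", "rs411103", 0.392, 3.82e-3, 0.41, 0.16, False),
        ("FLT4", "rs307806", 0.149, 3.85e-3, 0.46, 0.12, False),
        ("MMP2", "rs17859935", 0.169, 4.36e-3, 0.46, 0.14, False),
        ("ABCA1", "rs2472448", 0.106, 5.00e-3, 0.86, 0.46, True),
        ("VEGFA", "rs3025035", 0.072, 5.34e-3, 0.58, 0.13, False),
        ("PON1", "rs854555", 0.344, 6.22e-3, 0.41, 0.17, True),
        ("UCP1", "rs2043125", 0.265, 6.52e-3, 0.46, 0.17, False),
        ("PARP1", "rs3219065", 0.159, 7.75e-3, 0.41, 0.09, True),
        ("PARP1", "rs2027440", 0.159, 8.18e-3, 0.41, 0.08, True),
        ("MMP2", "rs17859970", 0.148, 9.99e-3, 0.43, 0.10, False),
    ],
    columns=[
        "gene",
        "snp_id",
        "maf",
        "p_value",
        "beta_naive",
        "beta_gw",
        "minor_allele_is_risk",
    ],
)

# Generating model of the simulation evaluation: the 15 common true-positive
# SNPs (MAF >= 5%) with their data-generated logHRs and risk-allele
# orientation (minor_allele_is_risk True => risk-allele frequency equals the
# MAF, else 1 - MAF). empirical_power is the reported detection frequency at
# the 5e-5 threshold, retained for reference.
GENERATING_MODEL_COMMON = pd.DataFrame(
    [
        (0.103, 0.50, False, 0.995),
        (0.349, 0.19, False, 0.773),
        (0.267, 0.22, True, 0.655),
        (0.171, 0.17, False, 0.557),
        (0.150, 0.13, False, 0.522),
        (0.137, 0.23, True, 0.500),
        (0.488, 0.27, True, 0.172),
        (0.390, 0.21, True, 0.100),
        (0.058, 0.19, True, 0.093),
        (0.158, 0.09, True, 0.089),
        (0.158, 0.13, True, 0.084),
        (0.146, 0.14, False, 0.007),
        (0.363, 0.14, False, 0.006),
        (0.068, 0.27, False, 0.002),
        (0.069, 0.12, False, 0.000),
    ],
    columns=["maf", "beta", "minor_allele_is_risk", "empirical_power"],
)

# Synthetic stand-in for the four low-frequency true positives
# (2% < MAF < 5%): their individual MAFs and logHRs were not reported, so
# representative values in the stated ranges were fixed once here. They model
# undetectable polygenic background and are excluded from the MAF >= 5%
# analysis panel.
LOW_FREQUENCY_TRUE_SNPS = pd.DataFrame(
    [
        (0.025, 0.35),
        (0.030, 0.28),
        (0.040, 0.22),
        (0.045, 0.30),
    ],
    columns=["maf", "beta"],
)

# Multivariable covariate effects of the generating model (logHR), estimated
# with stratification by year of trial entry.
COVARIATE_BETAS = {"sex": -0.59, "treatment": -1.48, "cohort": 0.73}


def risk_allele_frequency(panel: pd.DataFrame) -> np.ndarray:
    """Risk-allele frequency: MAF where the minor allele carries risk, else 1-MAF."""
    return np.where(
        panel["minor_allele_is_risk"].to_numpy(),
        panel["maf"].to_numpy(),
        1.0 - panel["maf"].to_numpy(),
    )
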