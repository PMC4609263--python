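"""Polygenic risk scores from selected-SNP logHR estimates.

An individual's score is the Cox linear predictor restricted to the scored
SNPs, S_i = sum_k beta_k g_ik with genotypes coded for the risk allele; the
hazard ratio between two individuals is exp(S_a - S_b). The population
expected score is S = sum_k beta_k q_k with q_k = 2 p_k the expected
risk-allele dosage under Hardy-Weinberg equilibrium (p_k the risk-allele
frequency). Because naive effect estimates of selected SNPs are inflated,
naive scores overstate risk spread; shrunken (bootstrap-corrected) weights
yield correspondingly shrunken scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import GenotypeMatrix

__all__ = ["RiskScorer", "individual_scores", "expected_score"]


def individual_scores(
    genotypes: GenotypeMatrix | np.ndarray, betas: np.ndarray
) -> pd.DataFrame:
    """Per-individual risk scores over the scored SNPs.

    Missing genotypes are not imputed: the score is the sum over the
    individual's observed scored SNPs and ``n_missing`` counts the omissions
    (rows with ``n_missing > 0`` are incomplete).
    """
    G = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else np.asarray(
        genotypes, dtype=float
    )
    betas = np.asarray(betas, dtype=float)
    if G.shape[1] != betas.shape[0]:
        raise ValueError("betas must cover exactly the scored SNPs")
    missing = np.isnan(G)
    contrib = np.where(missing, 0.0, G) * betas
    ids = (
        genotypes.sample_ids
        if isinstance(genotypes, GenotypeMatrix)
        else np.array([f"id{i+1}" for i in range(G.shape[0])], dtype=object)
    )
    return pd.DataFrame(
        {
            "id": ids,
            "score": contrib.sum(axis=1),
            "n_missing": missing.sum(axis=1).astype(int),
        }
    )


def expected_score(betas: np.ndarray, risk_allele_freqs: np.ndarray) -> float:
    """Population expected risk score sum_k beta_k * 2 p_k (HWE)."""
    betas = np.asarray(betas, dtype=float)
    p = np.asarray(risk_allele_freqs, dtype=float)
    if betas.shape != p.shape:
        raise ValueError("betas and risk_allele_freqs must align")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("risk allele frequencies must lie in [0, 1]")
    return float(np.sum(betas * 2.0 * p))


class RiskScorer(BaseEstimator, TransformerMixin):
    """Transformer mapping risk-allele-coded genotypes to risk scores.

    Parameters
    ----------
    betas : per-SNP logHRs of the risk allele (non-negative after orientation).
    snp_ids : optional SNP identifiers; when given together with a
        GenotypeMatrix input, columns are matched by id.
    """

    def __init__(self, betas=None, snp_ids=None):
        self.betas = betas
        self.snp_ids = snp_ids

    def fit(self, X=None, y=None):
        if self.betas is None:
            raise ValueError("RiskScorer requires betas")
        self.betas_ = np.asarray(self.betas, dtype=float)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "betas_"):
            self.fit()
        if isinstance(X, GenotypeMatrix) and self.snp_ids is not None:
            cols = np.array(
                [int(np.nonzero(X.snp_ids == s)[0][0]) for s in self.snp_ids]
            )
            X = X.subset_snps(cols)
        return individual_scores(X, self.betas_)
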