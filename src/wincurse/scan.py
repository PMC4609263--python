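"""Per-SNP Cox proportional-hazards association scan with threshold/rank selection.

Each SNP is fit one at a time in a (optionally covariate-adjusted, stratified)
Cox model with additive genotype coding; the Wald statistic beta/se is
referred to the standard normal for a two-sided p-value. SNPs passing the
selection rule (p < alpha, optionally capped at top_k) are ranked by ascending
p-value with ties broken by SNP id. Estimates for *all* SNPs are retained
because the bootstrap correction needs the original naive estimate of whatever
SNP a replicate happens to rank k-th.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special
from sklearn.base import BaseEstimator

from . import _coxfit
from .data import (
    AssocScanResult,
    GenotypeMatrix,
    SelectionRule,
    SurvivalPhenotype,
    recode_to_positive,
)

logger = logging.getLogger(__name__)

__all__ = ["CoxFit", "CoxSNPScan", "fit_cox", "scan_all", "wald_p"]


def wald_p(z: np.ndarray) -> np.ndarray:
    """Two-sided standard-normal tail probability 2*(1 - Phi(|z|))."""
    return special.erfc(np.abs(z) / np.sqrt(2.0))


@dataclass
class CoxFit:
    """A single Cox fit: logHR, its standard error and large-sample Wald test."""

    beta: float
    se: float
    wald_z: float
    p_value: float
    converged: bool
    n_events_used: int


def _as_phenotype(y) -> SurvivalPhenotype:
    if isinstance(y, SurvivalPhenotype):
        return y
    y = np.asarray(y)
    if y.dtype.names and {"time", "event"} <= set(y.dtype.names):
        return SurvivalPhenotype(time=y["time"], event=y["event"])
    raise TypeError(
        "y must be a SurvivalPhenotype or a structured array with fields "
        "('event', 'time')"
    )


def _as_genotypes(X) -> GenotypeMatrix:
    if isinstance(X, GenotypeMatrix):
        return X
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    ids = np.array([f"snp{j+1}" for j in range(m)], dtype=object)
    return GenotypeMatrix(X, ids, ids.copy())


def fit_cox(
    dosage: np.ndarray,
    phenotype: SurvivalPhenotype,
    covariates_included: bool = False,
    strata_included: bool = False,
    ties: str = "breslow",
) -> CoxFit:
    """Fit one SNP's additive Cox model, complete-case over missing dosages.

    Raises ValueError when the dosage is constant among complete cases or no
    events remain.
    """
    d = np.asarray(dosage, dtype=float)
    rows = ~np.isnan(d)
    ph = phenotype.subset(rows) if not rows.all() else phenotype
    d = d[rows]
    if not ph.event.any():
        raise ValueError("no events among complete cases")
    if d.max() == d.min():
        raise ValueError("constant dosage (degenerate covariate)")
    cols = [d[:, None]]
    if covariates_included and ph.covariates is not None:
        cols.append(ph.covariates)
    X = np.hstack(cols)
    stratum = ph.stratum if strata_included else None
    beta, cov, _, converged = _coxfit.general_fit(
        X, ph.time, ph.event, stratum=stratum, ties=ties
    )
    se = float(np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else np.nan
    z = beta[0] / se if se and np.isfinite(se) and se > 0 else np.nan
    return CoxFit(
        beta=float(beta[0]),
        se=se,
        wald_z=float(z),
        p_value=float(wald_p(z)) if np.isfinite(z) else np.nan,
        converged=bool(converged),
        n_events_used=ph.n_events,
    )


def _rank_selected(
    snp_ids: np.ndarray, p: np.ndarray, eligible: np.ndarray, rule: SelectionRule
) -> tuple[np.ndarray, np.ndarray]:
    """Selection mask and 1..K ranks (ascending p, ties by snp_id)."""
    m = p.shape[0]
    selected = eligible & np.where(np.isnan(p), False, p < rule.alpha)
    idx = np.nonzero(selected)[0]
    order = idx[np.lexsort((snp_ids[idx].astype(str), p[idx]))]
    if rule.top_k is not None and order.size > rule.top_k:
        dropped = order[rule.top_k :]
        selected[dropped] = False
        order = order[: rule.top_k]
    rank = np.full(m, np.nan)
    rank[order] = np.arange(1, order.size + 1)
    return selected, rank


class CoxSNPScan(BaseEstimator):
    """Mass-univariable Cox PH scan over a SNP panel.

    Parameters
    ----------
    alpha : float
        Two-sided significance threshold for selection.
    top_k : int, optional
        Cap on the number of ranked SNPs retained.
    use_covariates, use_strata : bool
        Adjust each fit for the phenotype's covariates / stratify its baseline.
        The default is the univariable scan (SNP only).
    ties : {"breslow", "efron"}
        Tie handling for the partial likelihood. The vectorised fast path is
        Breslow; Efron falls back to per-SNP fits.

    Attributes (after fit)
    ----------------------
    result_ : AssocScanResult
        Per-SNP estimates, recoded so every naive logHR is >= 0.
    genotypes_ : GenotypeMatrix
        The recoded panel (g -> 2-g wherever the raw estimate was negative).
    phenotype_ : SurvivalPhenotype
    """

    def __init__(
        self,
        alpha: float = 0.01,
        top_k: int | None = None,
        use_covariates: bool = False,
        use_strata: bool = False,
        ties: str = "breslow",
        precision: str = "exact",
    ):
        self.alpha = alpha
        self.top_k = top_k
        self.use_covariates = use_covariates
        self.use_strata = use_strata
        self.ties = ties
        self.precision = precision

    @property
    def rule_(self) -> SelectionRule:
        return SelectionRule(alpha=self.alpha, top_k=self.top_k)

    def fit(self, X, y):
        genotypes = _as_genotypes(X)
        phenotype = _as_phenotype(y)
        if genotypes.n_individuals != phenotype.n_individuals:
            raise ValueError("genotypes and phenotype cover different individuals")
        rule = self.rule_
        m = genotypes.n_snps
        stratum = phenotype.stratum if self.use_strata else None

        use_fast = self.ties == "breslow" and not (
            self.use_covariates and phenotype.covariates is not None
        )
        if use_fast:
            beta, se, _, conv, n_events = _coxfit.univariate_with_missing(
                genotypes.dosages, phenotype.time, phenotype.event, stratum,
                precision=self.precision,
            )
        else:
            beta = np.full(m, np.nan)
            se = np.full(m, np.nan)
            conv = np.zeros(m, dtype=bool)
            n_events = phenotype.n_events
            for j in range(m):
                try:
                    f = fit_cox(
                        genotypes.dosages[:, j],
                        phenotype,
                        covariates_included=self.use_covariates,
                        strata_included=self.use_strata,
                        ties=self.ties,
                    )
                except ValueError:
                    continue
                beta[j], se[j], conv[j] = f.beta, f.se, f.converged

        n_degen = int(np.isnan(beta).sum())
        if n_degen:
            logger.warning("%d SNP(s) skipped as degenerate/unfittable", n_degen)
        if (~conv & ~np.isnan(beta)).any():
            logger.warning(
                "%d SNP fit(s) did not converge; excluded from selection",
                int((~conv & ~np.isnan(beta)).sum()),
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
        p = np.where(conv, wald_p(z), np.nan)
        selected, rank = _rank_selected(genotypes.snp_ids, p, conv, rule)

        maf = np.array(
            [
                _safe_maf(genotypes.dosages[:, j])
                for j in range(m)
            ]
        )
        raw = AssocScanResult(
            snp_ids=genotypes.snp_ids.copy(),
            beta_naive=beta,
            se=se,
            p_value=p,
            maf=maf,
            recoded=np.zeros(m, dtype=bool),
            converged=conv,
            selected=selected,
            rank=rank,
            n_events=n_events,
            rule=rule,
        )
        self.genotypes_, self.result_ = recode_to_positive(genotypes, raw)
        self.phenotype_ = phenotype
        return self


def _safe_maf(col: np.ndarray) -> float:
    try:
        from .data import compute_maf

        return compute_maf(col)
    except ValueError:
        return np.nan


def scan_all(
    genotypes: GenotypeMatrix,
    phenotype: SurvivalPhenotype,
    rule: SelectionRule,
    use_covariates: bool = False,
    use_strata: bool = False,
    ties: str = "breslow",
) -> AssocScanResult:
    """Functional wrapper over :class:`CoxSNPScan`; returns the recoded scan."""
    est = CoxSNPScan(
        alpha=rule.alpha,
        top_k=rule.top_k,
        use_covariates=use_covariates,
        use_strata=use_strata,
        ties=ties,
    ).fit(genotypes, phenotype)
    return est.result_
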