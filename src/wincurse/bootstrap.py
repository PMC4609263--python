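"""Bootstrap winner's-curse bias reduction for Cox SNP scans.

The genome-wide (GW) corrector reruns the full scan inside each bootstrap
replicate: the n resampled-with-replacement individuals play the role of a
detection sample, the never-drawn individuals the role of an independent
estimation sample. The replicate's own ranked selection is matched to the
original selection *by rank* -- the replicate's k-th-ranked SNP may be a
different SNP -- and the average of the (within - adjusted out-of-sample)
differences, rescaled to the genotypic-variance scale of the original k-th
SNP, is subtracted from the original naive estimate and truncated at the null:

    beta*_boot(k) = max(0, beta_N(k)
                        - mean_i [ (beta_Di(k) - beta*_Ei(k))
                                   * sqrt(p_i(k)(1-p_i(k)) / p(k)(1-p(k))) ])

    beta*_Ei(k) = beta_Ei(k) - ratio(k) * (beta_Di(k) - beta_Ni(k))

where ratio(k) accounts for the negative correlation between within- and
out-of-sample estimates over a fixed total sample (empirical
cov(beta_D, beta_E)/var(beta_D) across replicates at rank k, by default),
p_i(k) is the original-data MAF of the replicate's k-th SNP, p(k) that of the
original k-th SNP, and beta_Ni(k) the original naive estimate of the SNP the
replicate ranked k-th. The average runs over the B(k) <= B replicates whose
own selection contains at least k SNPs (with a convergent out-of-sample fit).

The single-SNP (SS) comparator applies the same resampling to one SNP at a
time, averaging only the replicates in which that SNP itself is significant;
it corrects threshold-selection bias but not ranking competition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import _coxfit
from .data import (
    AssocScanResult,
    GenotypeMatrix,
    SelectionRule,
    SurvivalPhenotype,
    compute_maf,
)
from .scan import CoxSNPScan, wald_p, _rank_selected

logger = logging.getLogger(__name__)

__all__ = [
    "draw_replicate",
    "maf_rescale_factor",
    "correlation_adjust",
    "GWBootstrapCorrector",
    "gw_bias_reduce",
    "ss_bias_reduce",
    "gw_decomposition_diagnostic",
    "GWDecomposition",
]

RECORD_COLUMNS = [
    "replicate",
    "rank",
    "snp_id",
    "beta_within",
    "beta_out",
    "var_within",
    "var_out",
    "maf_replicate",
    "maf_within",
    "beta_orig_of_selected",
    "out_converged",
]


def draw_replicate(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap partition: n with-replacement draws and the left-out set.

    Deterministic given ``seed``. In the astronomically unlikely case that
    every individual is drawn (empty out-of-sample set), the draw is repeated
    with an incremented seed and a warning is logged.
    """
    if n < 2:
        raise ValueError("need at least 2 individuals to bootstrap")
    s = int(seed)
    while True:
        rng = np.random.default_rng(s)
        within = rng.integers(0, n, size=n)
        mask = np.zeros(n, dtype=bool)
        mask[within] = True
        out = np.nonzero(~mask)[0]
        if out.size:
            return within, out
        logger.warning("empty out-of-sample set at seed %d; redrawing", s)
        s += 1


def maf_rescale_factor(p_replicate: float, p_original: float) -> float:
    """sqrt(2 p_i (1-p_i)) / sqrt(2 p (1-p)).

    Converts a selection-bias increment measured on the replicate-selected SNP
    (genotypic SD sqrt(2 p_i (1-p_i))) to the scale of the originally selected
    SNP, since bias in a logHR is inversely proportional to the genotypic SD.
    """
    for p in (p_replicate, p_original):
        if not (0.0 < p <= 0.5):
            raise ValueError(f"MAF must be in (0, 0.5]: {p}")
    return float(
        np.sqrt((p_replicate * (1.0 - p_replicate)) / (p_original * (1.0 - p_original)))
    )


def correlation_adjust(
    beta_out: float, beta_within: float, beta_orig: float, ratio: float
) -> float:
    """beta*_E = beta_E - ratio * (beta_D - beta_N) for one replicate entry."""
    return beta_out - ratio * (beta_within - beta_orig)


def _empirical_ratio(bw: np.ndarray, bo: np.ndarray) -> float:
    """cov(beta_D, beta_E) / var(beta_D) across replicates; 0 when undefined."""
    if bw.size < 2:
        return 0.0
    var = np.var(bw, ddof=1)
    if var <= 0:
        return 0.0
    cov = np.cov(bw, bo, ddof=1)[0, 1]
    return float(cov / var)


def _fit_out_of_sample(dosage, time, event, stratum):
    """Univariable Breslow fit of one SNP on the out-of-sample individuals."""
    d = np.asarray(dosage, dtype=float)
    rows = ~np.isnan(d)
    d = d[rows]
    ev = np.asarray(event, bool)[rows]
    if not ev.any() or d.size == 0 or d.max() == d.min():
        return np.nan, np.nan, False
    strat = None if stratum is None else stratum[rows]
    b, s, _, c, _ = _coxfit.univariate_many(
        d[:, None].astype(np.int8), time[rows], ev, strat
    )
    return float(b[0]), float(s[0]), bool(c[0])


class GWBootstrapCorrector(BaseEstimator):
    """Genome-wide bootstrap bias-reduced logHR estimates for selected SNPs.

    Parameters
    ----------
    alpha, top_k : selection rule applied identically to the original scan and
        to every bootstrap replicate's rescan.
    B : int
        Number of bootstrap replicates (replicate i is seeded seed + i, so any
        single replicate is reproducible in isolation).
    top_fraction : float, optional
        Restrict per-replicate rescans to this top-ranked fraction of the
        original panel (ordered by original p-value).
    adjust : {"empirical", "hybrid", "none"}
        Correlation-adjustment ratio: empirical cross-replicate
        cov(D,E)/var(D) at each rank (default); "hybrid" rescales the
        empirical rank-level correlation by each replicate's model-based
        standard errors; "none" disables the adjustment.
    compute_ss : bool
        Also derive single-SNP bootstrap estimates for every originally
        selected SNP from the same replicate records.
    random_state : int

    Attributes (after fit)
    ----------------------
    estimates_ : DataFrame with one row per originally selected SNP (rank
        order): naive estimate, GW-corrected estimate, bias estimate, B_used,
        truncation flag, and (optionally) the SS estimate.
    records_ : DataFrame of per-replicate, per-rank bootstrap records.
    scan_ : the fitted CoxSNPScan for the original sample.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        top_k: int | None = None,
        B: int = 100,
        top_fraction: float | None = None,
        adjust: str = "empirical",
        compute_ss: bool = False,
        use_covariates: bool = False,
        use_strata: bool = False,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.top_k = top_k
        self.B = B
        self.top_fraction = top_fraction
        self.adjust = adjust
        self.compute_ss = compute_ss
        self.use_covariates = use_covariates
        self.use_strata = use_strata
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _rescan_columns(self, scan: AssocScanResult) -> np.ndarray:
        """Columns included in replicate rescans (all, or the top fraction)."""
        m = scan.snp_ids.shape[0]
        if self.top_fraction is None:
            return np.arange(m)
        keep = max(1, int(np.ceil(self.top_fraction * m)))
        p = np.where(np.isnan(scan.p_value), np.inf, scan.p_value)
        order = np.lexsort((scan.snp_ids.astype(str), p))
        cols = np.sort(order[:keep])
        # the originally selected SNPs are always rescanned
        return np.union1d(cols, np.nonzero(scan.selected)[0])

    def fit(self, X, y, scan: CoxSNPScan | None = None):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if scan is None:
            scan = CoxSNPScan(
                alpha=self.alpha,
                top_k=self.top_k,
                use_covariates=self.use_covariates,
                use_strata=self.use_strata,
            ).fit(X, y)
        self.scan_ = scan
        res = scan.result_
        genotypes = scan.genotypes_  # recoded panel: all naive estimates >= 0
        phenotype = scan.phenotype_
        rule = SelectionRule(alpha=self.alpha, top_k=self.top_k)
        n = phenotype.n_individuals
        K = res.n_selected
        sel_order = res.selected_order()
        stratum = phenotype.stratum if self.use_strata else None

        cols = self._rescan_columns(res)
        base_seed = int(self.random_state) % (2**31 - 1)
        records: list[tuple] = []
        G = genotypes.dosages
        Gcols = G[:, cols]
        snp_ids_cols = genotypes.snp_ids[cols]
        beta_orig_all = res.beta_naive  # recoded scale, >= 0 where defined
        maf_orig_all = res.maf
        # warm start for replicate rescans: within-sample estimates sit near
        # the original-sample ones
        warm = np.where(np.isfinite(beta_orig_all[cols]), beta_orig_all[cols], 0.0)
        complete = not np.isnan(Gcols).any()
        if complete:
            Gcols_i8 = Gcols.astype(np.int8)

        for i in range(1, self.B + 1):
            within, out = draw_replicate(n, base_seed + i)
            tw = phenotype.time[within]
            ew = phenotype.event[within]
            sw = None if stratum is None else stratum[within]
            if not ew.any():
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                if complete:
                    b, s, _, conv, _ = _coxfit.univariate_many(
                        Gcols_i8[within], tw, ew, sw, beta0=warm, precision="fast"
                    )
                else:
                    b, s, _, conv, _ = _coxfit.univariate_with_missing(
                        Gcols[within], tw, ew, sw, beta0=warm, precision="fast"
                    )
                p = np.where(conv, wald_p(b / s), np.nan)
            selected, rank = _rank_selected(snp_ids_cols, p, conv, rule)
            order = np.nonzero(selected)[0]
            order = order[np.argsort(rank[order])]
            if K:
                order = order[:K]  # only ranks up to the original K are used
            t_out = phenotype.time[out]
            e_out = phenotype.event[out]
            s_out = None if stratum is None else stratum[out]
            for k_rank, jc in enumerate(order, start=1):
                j = cols[jc]
                orient = 1.0 if b[jc] >= 0 else -1.0
                bo, so, cvg = _fit_out_of_sample(
                    G[out, j], t_out, e_out, s_out
                )
                col_w = Gcols[within, jc]
                try:
                    maf_within = compute_maf(col_w)
                except ValueError:
                    maf_within = np.nan
                # naive estimate of the replicate-selected SNP, read from the
                # original scan; 0 (null) if that SNP's original fit failed
                bn_j = beta_orig_all[j] if np.isfinite(beta_orig_all[j]) else 0.0
                records.append(
                    (
                        i,
                        k_rank,
                        genotypes.snp_ids[j],
                        orient * b[jc],
                        orient * bo if cvg else np.nan,
                        s[jc] ** 2,
                        so**2 if cvg else np.nan,
                        maf_orig_all[j],
                        maf_within,
                        orient * bn_j,
                        cvg,
                    )
                )
                if not cvg:
                    logger.warning(
                        "replicate %d rank %d (%s): out-of-sample fit failed",
                        i,
                        k_rank,
                        genotypes.snp_ids[j],
                    )

        self.records_ = pd.DataFrame(records, columns=RECORD_COLUMNS)
        self.estimates_ = self._estimates_from_records(res, sel_order)
        if self.compute_ss:
            self.estimates_["beta_ss"], self.estimates_["ss_B_used"] = zip(
                *[
                    _ss_from_records(
                        self.records_,
                        res.snp_ids[j],
                        beta_orig_all[j],
                        maf_orig_all[j],
                        self.adjust,
                    )
                    for j in sel_order
                ]
            ) if len(sel_order) else ((), ())
        return self

    def _estimates_from_records(
        self, res: AssocScanResult, sel_order: np.ndarray
    ) -> pd.DataFrame:
        rows = []
        rec = self.records_
        for k, j in enumerate(sel_order, start=1):
            rk = rec[(rec["rank"] == k) & rec["out_converged"]]
            bw = rk["beta_within"].to_numpy()
            bo = rk["beta_out"].to_numpy()
            bn_i = rk["beta_orig_of_selected"].to_numpy()
            if self.adjust == "none":
                ratio = 0.0
                bo_star = bo
            elif self.adjust == "hybrid":
                rho = _empirical_corr(bw, bo)
                sd = np.sqrt(rk["var_out"].to_numpy() / rk["var_within"].to_numpy())
                bo_star = bo - rho * sd * (bw - bn_i)
                ratio = np.nan
            else:
                ratio = _empirical_ratio(bw, bo)
                bo_star = bo - ratio * (bw - bn_i)
            factors = np.array(
                [
                    maf_rescale_factor(pi, res.maf[j])
                    for pi in rk["maf_replicate"].to_numpy()
                ]
            )
            diffs = (bw - bo_star) * factors
            B_used = int(diffs.size)
            if B_used == 0:
                logger.warning(
                    "rank %d (%s): no usable replicates; GW estimate undefined",
                    k,
                    res.snp_ids[j],
                )
                bias = np.nan
                beta_gw = np.nan
                truncated = False
            else:
                bias = float(diffs.mean())
                raw = res.beta_naive[j] - bias
                truncated = raw < 0
                beta_gw = max(raw, 0.0)
            rows.append(
                {
                    "rank": k,
                    "snp_id": res.snp_ids[j],
                    "maf": res.maf[j],
                    "beta_naive": res.beta_naive[j],
                    "se": res.se[j],
                    "p_value": res.p_value[j],
                    "beta_gw": beta_gw,
                    "bias_estimate": bias,
                    "B_used": B_used,
                    "truncated": truncated,
                    "ratio": ratio,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "rank",
                "snp_id",
                "maf",
                "beta_naive",
                "se",
                "p_value",
                "beta_gw",
                "bias_estimate",
                "B_used",
                "truncated",
                "ratio",
            ],
        )


def _empirical_corr(bw: np.ndarray, bo: np.ndarray) -> float:
    if bw.size < 2 or np.std(bw) == 0 or np.std(bo) == 0:
        return 0.0
    return float(np.corrcoef(bw, bo)[0, 1])


def _ss_from_records(
    records: pd.DataFrame,
    snp_id: str,
    beta_orig: float,
    maf_orig: float,
    adjust: str = "empirical",
) -> tuple[float, int]:
    """Single-SNP estimate from GW records (replicates where the SNP was
    itself significant are exactly those whose selection contains it)."""
    rk = records[(records["snp_id"] == snp_id) & records["out_converged"]]
    bw = rk["beta_within"].to_numpy()
    bo = rk["beta_out"].to_numpy()
    bn = rk["beta_orig_of_selected"].to_numpy()
    if bw.size == 0:
        return np.nan, 0
    ratio = 0.0 if adjust == "none" else _empirical_ratio(bw, bo)
    bo_star = bo - ratio * (bw - bn)
    factors = np.array(
        [
            maf_rescale_factor(pi, maf_orig) if np.isfinite(pi) else 1.0
            for pi in rk["maf_within"].to_numpy()
        ]
    )
    bias = float(((bw - bo_star) * factors).mean())
    return max(beta_orig - bias, 0.0), int(bw.size)


def gw_bias_reduce(
    genotypes: GenotypeMatrix,
    phenotype: SurvivalPhenotype,
    rule: SelectionRule,
    B: int = 100,
    seed: int = 0,
    **kw,
) -> pd.DataFrame:
    """Functional wrapper: scan + GW bootstrap; returns the estimates table."""
    est = GWBootstrapCorrector(
        alpha=rule.alpha,
        top_k=rule.top_k,
        top_fraction=rule.top_fraction,
        B=B,
        random_state=seed,
        **kw,
    ).fit(genotypes, phenotype)
    return est.estimates_


def ss_bias_reduce(
    snp_id: str,
    genotypes: GenotypeMatrix,
    phenotype: SurvivalPhenotype,
    rule: SelectionRule,
    B: int = 100,
    seed: int = 0,
    scan: CoxSNPScan | None = None,
) -> tuple[float, int]:
    """Single-SNP bootstrap bias-reduced estimate for one selected SNP.

    Per replicate, only this SNP is fit within-sample; replicates where its
    Wald p-value beats the threshold contribute (beta_D - beta*_E) differences
    (correlation-adjusted against the SNP's own original naive estimate and
    rescaled by its within-replicate vs original MAF). Returns (estimate,
    number of qualifying replicates); the estimate is NaN when none qualify.
    """
    if scan is None:
        scan = CoxSNPScan(alpha=rule.alpha, top_k=rule.top_k).fit(genotypes, phenotype)
    res = scan.result_
    j = res.index_of(snp_id)
    if not res.selected[j]:
        raise ValueError(f"{snp_id} was not selected in the original scan")
    G = scan.genotypes_.dosages[:, j]
    ph = scan.phenotype_
    n = ph.n_individuals
    base_seed = int(seed) % (2**31 - 1)
    bws, bos, bns, facs = [], [], [], []
    for i in range(1, B + 1):
        within, out = draw_replicate(n, base_seed + i)
        bw, sw, cw = _fit_out_of_sample(G[within], ph.time[within], ph.event[within], None)
        if not cw or not np.isfinite(bw):
            continue
        if wald_p(bw / sw) >= rule.alpha:
            continue
        bo, so, co = _fit_out_of_sample(G[out], ph.time[out], ph.event[out], None)
        if not co:
            logger.warning("SS replicate %d: out-of-sample fit failed", i)
            continue
        orient = 1.0 if bw >= 0 else -1.0
        try:
            maf_w = compute_maf(G[within])
            fac = maf_rescale_factor(maf_w, res.maf[j])
        except ValueError:
            fac = 1.0
        bws.append(orient * bw)
        bos.append(orient * bo)
        bns.append(orient * res.beta_naive[j])
        facs.append(fac)
    if not bws:
        logger.warning("SS bootstrap: no qualifying replicates for %s", snp_id)
        return np.nan, 0
    bw = np.array(bws)
    bo = np.array(bos)
    bn = np.array(bns)
    ratio = _empirical_ratio(bw, bo)
    bo_star = bo - ratio * (bw - bn)
    bias = float(((bw - bo_star) * np.array(facs)).mean())
    return max(res.beta_naive[j] - bias, 0.0), len(bws)


@dataclass
class GWDecomposition:
    """Rank-1 split of the GW bias estimate by replicate-selected identity."""

    B_C: int
    B_Cstar: int
    delta_C: float
    delta_Cstar: float

    @property
    def delta_GW(self) -> float:
        B = self.B_C + self.B_Cstar
        if B == 0:
            return np.nan
        total = 0.0
        if self.B_C:
            total += self.B_C / B * self.delta_C
        if self.B_Cstar:
            total += self.B_Cstar / B * self.delta_Cstar
        return total


def gw_decomposition_diagnostic(
    records: pd.DataFrame, snp_id: str
) -> GWDecomposition:
    """Split rank-1 replicate differences by whether the replicate's top SNP
    is the original top SNP (concordant, B_C) or a different one (B_C*).

    Diagnostic only: differences are raw beta_within - beta_out, with no
    correlation adjustment or MAF rescaling.
    """
    r1 = records[(records["rank"] == 1) & records["out_converged"]]
    conc = r1["snp_id"] == snp_id
    d = (r1["beta_within"] - r1["beta_out"]).to_numpy()
    dc = d[conc.to_numpy()]
    ds = d[~conc.to_numpy()]
    return GWDecomposition(
        B_C=int(dc.size),
        B_Cstar=int(ds.size),
        delta_C=float(dc.mean()) if dc.size else np.nan,
        delta_Cstar=float(ds.mean()) if ds.size else np.nan,
    )
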