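"""Repeated generate-scan-correct simulation studies.

Each replicate draws a fresh dataset from a :class:`~wincurse.simulate.SimSpec`,
runs the univariable scan over the MAF-filtered analysis panel (deliberately
misspecified: generation is multivariable, analysis is one SNP at a time),
and applies the requested bias-reduction estimators to the selected SNPs.
Because of the misspecification the bias reference for a true SNP is its mean
fitted marginal logHR over *all* replicates, not its generating value;
empirical power is the fraction of replicates in which the SNP's Wald test
passes the threshold. Selected SNPs outside the generating model are false
positives; those sharing a gene block with, or in LD (r^2 > 0.2) with, a
generating SNP are excluded from the false-positive distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import GWBootstrapCorrector
from .conditional import ConditionalModel, compromise_estimate
from .data import SelectionRule
from .scan import CoxSNPScan
from .simulate import SimSpec, assemble_dataset

logger = logging.getLogger(__name__)

__all__ = ["StudySummary", "run_study", "ld_r2", "false_positive_table"]

DEFAULT_FP_BINS = (0.05, 0.10, 0.20, 0.35, 0.501)
LD_EXCLUSION_R2 = 0.2


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of two dosage vectors."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2 or a.std() == 0 or b.std() == 0:
        raise ValueError("dosage vectors must be non-constant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class StudySummary:
    """Accumulated results of a simulation study."""

    true_snps: pd.DataFrame
    false_positives: pd.DataFrame
    records: pd.DataFrame
    n_replicates: int
    n_events_mean: float
    rule: SelectionRule
    estimators: tuple

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"StudySummary({self.n_replicates} replicates, "
            f"{len(self.true_snps)} true SNPs, mean events "
            f"{self.n_events_mean:.1f})"
        )


def _is_linked(g_fp: np.ndarray, true_cols: np.ndarray, G: np.ndarray) -> bool:
    for j in true_cols:
        try:
            if ld_r2(g_fp, G[:, j]) > LD_EXCLUSION_R2:
                return True
        except ValueError:
            continue
    return False


def false_positive_table(
    records: pd.DataFrame,
    bins=DEFAULT_FP_BINS,
    estimators=("naive", "gw"),
) -> pd.DataFrame:
    """Bin retained false-positive selections by MAF; mean estimate per bin.

    ``records`` must carry columns is_true, excluded, maf and one estimate
    column per estimator. Rows flagged excluded (gene-block sharing or
    r^2 > 0.2 with a generating SNP) are dropped.
    """
    fp = records[(~records["is_true"]) & (~records["excluded"])]
    edges = np.asarray(bins, dtype=float)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        rows = fp[(fp["maf"] >= lo) & (fp["maf"] < hi)]
        entry = {"maf_lo": lo, "maf_hi": hi, "n": len(rows)}
        for est in estimators:
            col = rows[est].dropna()
            entry[f"mean_{est}"] = float(col.mean()) if len(col) else np.nan
            entry[f"sd_{est}"] = float(col.std(ddof=1)) if len(col) > 1 else np.nan
        out.append(entry)
    return pd.DataFrame(out)


def run_study(
    spec: SimSpec,
    n_replicates: int,
    rule: SelectionRule,
    estimators=("naive", "gw", "ss", "cl"),
    B: int = 50,
    seed: int = 0,
    min_maf: float = 0.05,
    fp_bins=DEFAULT_FP_BINS,
    progress: bool = False,
) -> StudySummary:
    """Run a full generate-scan-correct study; reproducible given ``seed``.

    Per replicate: dataset from ``spec``; univariable scan of the MAF-filtered
    panel; for selected SNPs, GW bootstrap (and, derived from its records, the
    single-SNP bootstrap) plus the conditional-likelihood compromise estimate.
    Replicates selecting no SNP still contribute to empirical power and mean
    fitted logHR denominators.
    """
    bad = set(estimators) - {"naive", "gw", "ss", "cl"}
    if bad:
        raise ValueError(f"unknown estimators: {sorted(bad)}")
    need_boot = bool({"gw", "ss"} & set(estimators))
    nominal_maf = spec.nominal_maf()
    analysis_cols = np.nonzero(nominal_maf >= min_maf)[0]
    true_cols_full = np.array(sorted(spec.true_snps), dtype=int)
    # positions of analysed true SNPs within the analysis panel
    pos_in_panel = {j: k for k, j in enumerate(analysis_cols)}
    true_panel = [(j, pos_in_panel[j]) for j in true_cols_full if j in pos_in_panel]

    root = np.random.SeedSequence(int(seed))
    child_seeds = [
        int(c.generate_state(1)[0] % (2**31 - 1)) for c in root.spawn(n_replicates)
    ]

    n_true = len(true_panel)
    fitted = np.zeros((n_replicates, n_true))
    sig = np.zeros((n_replicates, n_true), dtype=bool)
    events = np.zeros(n_replicates)
    sel_rows: list[dict] = []

    for r in range(n_replicates):
        genotypes, phenotype = assemble_dataset(spec, child_seeds[r])
        panel = genotypes.subset_snps(analysis_cols)
        scan = CoxSNPScan(
            alpha=rule.alpha, top_k=rule.top_k, precision="fast"
        ).fit(panel, phenotype)
        res = scan.result_
        events[r] = res.n_events
        for t_idx, (j_full, k_panel) in enumerate(true_panel):
            b = res.beta_naive[k_panel]
            if res.recoded[k_panel]:
                b = -b  # back to the coded-allele (generating) orientation
            fitted[r, t_idx] = b if np.isfinite(b) else 0.0
            sig[r, t_idx] = (
                res.converged[k_panel]
                and np.isfinite(res.p_value[k_panel])
                and res.p_value[k_panel] < rule.alpha
            )

        if res.n_selected == 0:
            continue
        est_df = None
        if need_boot:
            corr = GWBootstrapCorrector(
                alpha=rule.alpha,
                top_k=rule.top_k,
                top_fraction=rule.top_fraction,
                B=B,
                compute_ss="ss" in estimators,
                random_state=child_seeds[r] ^ 0x5B00C5,
            ).fit(panel, phenotype, scan=scan)
            est_df = corr.estimates_.set_index("snp_id")

        true_ids = {panel.snp_ids[k] for _, k in true_panel}
        sel_order = res.selected_order()
        Gd = panel.dosages
        true_cols_panel = np.array([k for _, k in true_panel], dtype=int)
        for k_panel in sel_order:
            sid = res.snp_ids[k_panel]
            is_true = sid in true_ids
            excluded = False
            if not is_true:
                same_block = panel.gene_block[k_panel] in set(
                    panel.gene_block[true_cols_panel]
                )
                excluded = same_block or _is_linked(
                    Gd[:, k_panel], true_cols_panel, Gd
                )
            row = {
                "replicate": r,
                "snp_id": sid,
                "is_true": is_true,
                "excluded": excluded,
                "maf": res.maf[k_panel],
                "naive": res.beta_naive[k_panel],
                "gw": np.nan,
                "ss": np.nan,
                "cl": np.nan,
            }
            if est_df is not None and sid in est_df.index:
                row["gw"] = est_df.at[sid, "beta_gw"]
                if "beta_ss" in est_df.columns:
                    row["ss"] = est_df.at[sid, "beta_ss"]
            if "cl" in estimators:
                try:
                    row["cl"] = compromise_estimate(
                        ConditionalModel.from_alpha(
                            res.beta_naive[k_panel], res.se[k_panel], rule.alpha
                        )
                    )
                except ValueError:
                    pass
            sel_rows.append(row)
        if progress and (r + 1) % 10 == 0:  # pragma: no cover
            logger.info("replicate %d/%d done", r + 1, n_replicates)

    records = pd.DataFrame(
        sel_rows,
        columns=[
            "replicate",
            "snp_id",
            "is_true",
            "excluded",
            "maf",
            "naive",
            "gw",
            "ss",
            "cl",
        ],
    )

    true_rows = []
    for t_idx, (j_full, k_panel) in enumerate(true_panel):
        # snp ids are stable across replicates (same spec ordering)
        sid = f"snp{analysis_cols[k_panel] + 1}"
        mean_fitted = float(fitted[:, t_idx].mean())
        sel = records[(records["snp_id"] == sid) & records["is_true"]]
        entry = {
            "snp_id": sid,
            "maf": nominal_maf[j_full],
            "beta_generating": spec.true_snps[j_full],
            "empirical_power": float(sig[:, t_idx].mean()),
            "mean_fitted_logHR": mean_fitted,
            "n_selected": len(sel),
        }
        for est in estimators:
            col = sel[est].dropna() if est in sel.columns else pd.Series(dtype=float)
            entry[f"mean_bias_{est}"] = (
                float(col.mean() - mean_fitted) if len(col) else np.nan
            )
        true_rows.append(entry)

    fp_table = false_positive_table(
        records,
        bins=fp_bins,
        estimators=[e for e in estimators if e in ("naive", "gw", "ss", "cl")],
    ) if len(records) else pd.DataFrame()

    return StudySummary(
        true_snps=pd.DataFrame(true_rows),
        false_positives=fp_table,
        records=records,
        n_replicates=n_replicates,
        n_events_mean=float(events.mean()),
        rule=rule,
        estimators=tuple(estimators),
    )
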