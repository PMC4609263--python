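"""Domain containers and text-file I/O for genotype panels and survival phenotypes.

Genotypes are additively coded dosages (0/1/2 copies of the coded allele) for
``n`` individuals by ``m`` SNPs, with each SNP assigned to exactly one
candidate-gene block. Missing dosages are stored as NaN and handled by per-SNP
complete-case analysis downstream. Phenotypes are right-censored event times in
years with an event indicator, optional covariates, and an optional stratum
label used for stratified baseline hazards.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SurvivalPhenotype",
    "SelectionRule",
    "AssocScanResult",
    "compute_maf",
    "recode_to_positive",
    "load_genotypes",
    "write_genotypes",
    "load_phenotype",
    "write_phenotype",
    "write_results",
    "GenotypeParseError",
]


class GenotypeParseError(ValueError):
    """Raised for malformed genotype files (wrong row length, bad dosage)."""


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from a vector of additive dosages.

    The frequency of the coded allele among non-missing entries is
    ``mean(dosage)/2``; the minor allele frequency is ``min(f, 1-f)``.

    Raises
    ------
    ValueError
        If every entry is missing.
    """
    d = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("cannot compute MAF: all dosages missing")
    f = float(d[ok].mean()) / 2.0
    return min(f, 1.0 - f)


@dataclass
class GenotypeMatrix:
    """Additively coded dosage matrix with SNP metadata.

    Parameters
    ----------
    dosages : (n, m) float array
        Entries in {0, 1, 2} or NaN for missing.
    snp_ids : (m,) array of str
    gene_block : (m,) array of str
        Candidate-gene region label; every SNP belongs to exactly one block.
    sample_ids : (n,) array of str, optional
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    gene_block: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.gene_block = np.asarray(self.gene_block, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (n, m) array")
        n, m = self.dosages.shape
        if self.snp_ids.shape != (m,) or self.gene_block.shape != (m,):
            raise ValueError("snp_ids and gene_block must have one entry per SNP")
        if len(set(self.snp_ids)) != m:
            raise ValueError("snp_ids must be unique")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"id{i+1}" for i in range(n)], dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if self.sample_ids.shape != (n,):
                raise ValueError("sample_ids must have one entry per individual")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage outside {{0,1,2,missing}}: {bad!r}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing entries."""
        return np.array([compute_maf(self.dosages[:, j]) for j in range(self.n_snps)])

    @property
    def coded_allele_is_minor(self) -> np.ndarray:
        """True where the coded allele is the less frequent one."""
        with np.errstate(invalid="ignore"):
            f = np.nanmean(self.dosages, axis=0) / 2.0
        return f <= 0.5

    def column(self, snp_id: str) -> np.ndarray:
        j = int(np.nonzero(self.snp_ids == snp_id)[0][0])
        return self.dosages[:, j]

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, index],
            self.snp_ids[index],
            self.gene_block[index],
            self.sample_ids,
        )

    def subset_individuals(self, rows: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[rows], self.snp_ids, self.gene_block, self.sample_ids[rows]
        )


@dataclass
class SurvivalPhenotype:
    """Right-censored time-to-event phenotype with optional covariates/strata."""

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: Sequence[str] | None = None
    stratum: np.ndarray | None = None
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event).astype(bool)
        n = self.time.shape[0]
        if self.event.shape != (n,):
            raise ValueError("time and event must have equal length")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("all event/censoring times must be positive and finite")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise ValueError("covariates must have one row per individual")
            if self.covariate_names is None:
                self.covariate_names = [
                    f"x{k+1}" for k in range(self.covariates.shape[1])
                ]
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum, dtype=object)
            if self.stratum.shape != (n,):
                raise ValueError("stratum must have one entry per individual")
        if self.sample_ids is None:
            self.sample_ids = np.array([f"id{i+1}" for i in range(n)], dtype=object)
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)

    @property
    def n_individuals(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def strata_labels(self) -> np.ndarray:
        if self.stratum is None:
            return np.array(["_all"], dtype=object)
        return np.array(sorted(set(self.stratum)), dtype=object)

    def subset(self, rows: np.ndarray) -> "SurvivalPhenotype":
        return SurvivalPhenotype(
            time=self.time[rows],
            event=self.event[rows],
            covariates=None if self.covariates is None else self.covariates[rows],
            covariate_names=self.covariate_names,
            stratum=None if self.stratum is None else self.stratum[rows],
            sample_ids=self.sample_ids[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.sample_ids,
                "time": self.time,
                "event": self.event.astype(int),
                "stratum": self.stratum
                if self.stratum is not None
                else np.repeat("_all", self.n_individuals),
            }
        )
        if self.covariates is not None:
            for k, name in enumerate(self.covariate_names):
                df[name] = self.covariates[:, k]
        return df


@dataclass(frozen=True)
class SelectionRule:
    """Which SNPs count as 'selected' in a scan.

    alpha is the two-sided significance threshold on the Wald p-value; top_k
    optionally caps the number of ranked SNPs kept; top_fraction optionally
    restricts bootstrap rescans to the top-ranked fraction of the original
    panel.
    """

    alpha: float = 0.01
    top_k: int | None = None
    top_fraction: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1]: {self.alpha}")
        if self.top_k is not None and self.top_k < 1:
            raise ValueError("top_k must be >= 1 when given")
        if self.top_fraction is not None and not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass
class AssocScanResult:
    """Per-SNP naive Cox scan results after positive recoding.

    ``beta_naive`` is the logHR per copy of the (possibly recoded) coded
    allele, oriented so that every estimate is non-negative; ``recoded`` marks
    SNPs whose genotype was flipped (g -> 2-g). ``rank`` is 1..K by ascending
    p-value among selected SNPs (ties broken by snp_id), NaN elsewhere.
    """

    snp_ids: np.ndarray
    beta_naive: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    maf: np.ndarray
    recoded: np.ndarray
    converged: np.ndarray
    selected: np.ndarray
    rank: np.ndarray
    n_events: int
    rule: SelectionRule

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def selected_order(self) -> np.ndarray:
        """Column indices of selected SNPs in rank order."""
        idx = np.nonzero(self.selected)[0]
        return idx[np.argsort(self.rank[idx])]

    def index_of(self, snp_id: str) -> int:
        return int(np.nonzero(self.snp_ids == snp_id)[0][0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "maf": self.maf,
                "beta_naive": self.beta_naive,
                "se": self.se,
                "p_value": self.p_value,
                "recoded": self.recoded,
                "converged": self.converged,
                "selected": self.selected,
                "rank": self.rank,
            }
        )


def recode_to_positive(
    genotypes: GenotypeMatrix, scan: AssocScanResult
) -> tuple[GenotypeMatrix, AssocScanResult]:
    """Flip dosages (g -> 2-g) for SNPs with negative naive estimates.

    By the reparameterisation symmetry of the Cox partial likelihood the
    refitted logHR is exactly the sign-flipped estimate, so the scan's betas
    are negated in place of a refit. Returns the recoded matrix and an updated
    scan with all ``beta_naive >= 0`` and ``recoded`` flags set.
    """
    flip = scan.beta_naive < 0
    dos = genotypes.dosages.copy()
    dos[:, flip] = 2.0 - dos[:, flip]
    new_g = GenotypeMatrix(
        dos, genotypes.snp_ids, genotypes.gene_block, genotypes.sample_ids
    )
    new_scan = dataclasses.replace(
        scan,
        beta_naive=np.where(flip, -scan.beta_naive, scan.beta_naive),
        recoded=scan.recoded ^ flip,
    )
    return new_g, new_scan


# ---------------------------------------------------------------------------
# Text I/O (PLINK .raw-style additive dosage, tab-delimited phenotype/results)
# ---------------------------------------------------------------------------

_PLINK_RAW_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _parse_dosage_token(tok: str, lineno: int) -> float:
    if tok in ("NA", "na", "-9", "."):
        return np.nan
    try:
        v = float(tok)
    except ValueError as exc:
        raise GenotypeParseError(f"line {lineno}: unparsable dosage {tok!r}") from exc
    if v not in (0.0, 1.0, 2.0):
        raise GenotypeParseError(f"line {lineno}: dosage outside {{0,1,2,NA}}: {tok!r}")
    return v


def load_genotypes(
    path: str, map_path: str | None = None, format_dialect: str = "simple"
) -> GenotypeMatrix:
    """Read an additive text dosage file plus an optional SNP map.

    Dialects
    --------
    ``simple``
        Header row of SNP ids preceded by an ``id`` column; one row per
        individual: id then m dosages in {0,1,2,NA}.
    ``plink-raw``
        PLINK ``--recode A`` layout: FID IID PAT MAT SEX PHENOTYPE then one
        column per SNP (header names like ``rs123_A`` are stripped of the
        allele suffix).

    The map file is tab-delimited ``snp_id<TAB>gene_block``; without one,
    every SNP is placed in its own block.
    """
    if format_dialect not in ("simple", "plink-raw"):
        raise ValueError(f"unknown genotype dialect: {format_dialect!r}")
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise GenotypeParseError("empty genotype file")
        if format_dialect == "simple":
            n_lead = 1
            snp_ids = header[1:]
        else:
            n_lead = len(_PLINK_RAW_LEAD)
            if [h.upper() for h in header[:n_lead]] != _PLINK_RAW_LEAD:
                raise GenotypeParseError(
                    "plink-raw dialect expects header starting FID IID PAT MAT SEX PHENOTYPE"
                )
            snp_ids = [h.rsplit("_", 1)[0] if "_" in h else h for h in header[n_lead:]]
        m = len(snp_ids)
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != n_lead + m:
                raise GenotypeParseError(
                    f"line {lineno}: expected {n_lead + m} fields, found {len(toks)}"
                )
            ids.append(toks[1] if format_dialect == "plink-raw" else toks[0])
            rows.append([_parse_dosage_token(t, lineno) for t in toks[n_lead:]])
    dosages = np.array(rows, dtype=float).reshape(len(rows), m)
    if map_path is not None:
        mp = pd.read_csv(map_path, sep="\t", header=None, names=["snp_id", "gene_block"])
        block_of = dict(zip(mp["snp_id"].astype(str), mp["gene_block"].astype(str)))
        missing = [s for s in snp_ids if s not in block_of]
        if missing:
            raise GenotypeParseError(f"SNPs absent from map file: {missing[:5]}")
        blocks = [block_of[s] for s in snp_ids]
    else:
        blocks = list(snp_ids)
    return GenotypeMatrix(dosages, np.array(snp_ids), np.array(blocks), np.array(ids))


def write_genotypes(
    genotypes: GenotypeMatrix, path: str, map_path: str | None = None
) -> None:
    """Write the ``simple`` dialect (id + header of SNP ids) and optional map."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(map(str, genotypes.snp_ids)) + "\n")
        for i in range(genotypes.n_individuals):
            row = [
                "NA" if np.isnan(v) else str(int(v)) for v in genotypes.dosages[i]
            ]
            fh.write(str(genotypes.sample_ids[i]) + "\t" + "\t".join(row) + "\n")
    if map_path is not None:
        with open(map_path, "w") as fh:
            for s, b in zip(genotypes.snp_ids, genotypes.gene_block):
                fh.write(f"{s}\t{b}\n")


def load_phenotype(path: str) -> SurvivalPhenotype:
    """Read a tab-delimited phenotype table: id, time, event, stratum, covariates..."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file must contain columns {sorted(required)}")
    cov_cols = [c for c in df.columns if c not in ("id", "time", "event", "stratum")]
    return SurvivalPhenotype(
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(),
        covariates=df[cov_cols].to_numpy(float) if cov_cols else None,
        covariate_names=cov_cols or None,
        stratum=df["stratum"].to_numpy(object) if "stratum" in df.columns else None,
        sample_ids=df["id"].astype(str).to_numpy(object),
    )


def write_phenotype(phenotype: SurvivalPhenotype, path: str) -> None:
    phenotype.to_frame().to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path: str) -> None:
    """Write a results table (tab-delimited, UTF-8, header row)."""
    results.to_csv(path, sep="\t", index=False)
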