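"""SNP genotype containers, file readers, quality control and genomic inbreeding.

Genotypes are counts of a reference allele (A1), coded 0/1/2 with missing
entries stored as NaN. Two plain-text dialects are supported: PLINK ``.raw``
(additive recoding, whitespace separated) and a simple TSV matrix with a
header row of SNP ids and a first column of individual ids.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

MISSING_TOKENS = ("NA", "-9", "")

_VALID_CODES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs reference-allele counts with NaN for missing."""

    values: np.ndarray
    individual_ids: np.ndarray
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        n, m = self.values.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match matrix rows")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length does not match matrix columns")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.isin(obs, _VALID_CODES).all():
            raise ValueError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_snps) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            self.values[np.ix_(rows, cols)],
            self.individual_ids[rows],
            self.snp_ids[cols],
        )


@dataclass
class QCThresholds:
    """Marker/individual filters; values are proportions in [0, 1].

    Defaults mirror the conventional preGSf90-style defaults: minor allele
    frequency >= 0.05, SNP and individual call rates >= 0.90, and a
    Hardy-Weinberg filter removing SNPs whose observed heterozygote
    frequency deviates from 2pq by more than 0.15.
    """

    maf: float = 0.05
    snp_call_rate: float = 0.90
    ind_call_rate: float = 0.90
    hwe_het_deviation: float = 0.15

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"QC threshold {name}={v} outside [0, 1]")


@dataclass
class QCReport:
    n_individuals_in: int
    n_individuals_out: int
    n_snps_in: int
    n_snps_out: int
    removed_individual_call_rate: int
    removed_snp_call_rate: int
    removed_maf: int
    removed_hwe: int
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _parse_genotype_frame(df: pd.DataFrame) -> np.ndarray:
    """Coerce a frame of genotype tokens to float codes; invalid tokens -> NaN."""
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isnan(arr) & ~np.isin(arr, _VALID_CODES)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} genotype tokens outside {{0,1,2}} set to missing")
        arr[bad] = np.nan
    return arr


def read_genotypes(path, format: str = "matrix-tsv") -> GenotypeMatrix:
    """Read genotypes from ``matrix-tsv`` or ``plink-raw`` text files.

    Missing tokens are "NA", "-9" and empty fields; any other unparseable
    or out-of-range token is set to missing with a warning.
    """
    if format == "matrix-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         na_values=list(MISSING_TOKENS), keep_default_na=False)
        ids = df.index.astype(str).to_numpy(dtype=object)
        snps = df.columns.astype(str).to_numpy(dtype=object)
        values = _parse_genotype_frame(df)
    elif format == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str,
                         na_values=list(MISSING_TOKENS), keep_default_na=False)
        lead = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != lead:
            raise ValueError(
                "malformed plink-raw header: expected leading columns "
                f"{lead}, got {list(df.columns[:6])}"
            )
        ids = df["IID"].astype(str).to_numpy(dtype=object)
        geno = df.iloc[:, 6:]
        # strip the _<allele> suffix plink appends to each SNP name
        snps = np.array([c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns],
                        dtype=object)
        values = _parse_genotype_frame(geno)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    return GenotypeMatrix(values, ids, snps)


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write the matrix-tsv dialect that :func:`read_genotypes` accepts."""
    df = pd.DataFrame(g.values, index=g.individual_ids, columns=g.snp_ids)
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "id"
    out.to_csv(path, sep="\t")


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Observed frequency of allele A1 per SNP, missing genotypes excluded."""
    obs = ~g.missing_mask
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = g.snp_ids[np.where(n_obs == 0)[0][0]]
        raise ValueError(f"SNP {bad!r} has no non-missing genotypes")
    return np.nansum(g.values, axis=0) / (2.0 * n_obs)


def genomic_inbreeding(g: GenotypeMatrix) -> pd.Series:
    """Per-individual homozygosity: fraction of non-missing SNPs not heterozygous.

    This is the covariate f of the inbreeding-depression term; it is a raw
    observed proportion, not an identity-by-descent estimate.
    """
    obs = ~g.missing_mask
    n_obs = obs.sum(axis=1)
    if (n_obs == 0).any():
        bad = g.individual_ids[np.where(n_obs == 0)[0][0]]
        raise ValueError(f"individual {bad!r} has no non-missing genotypes")
    het = np.nansum(g.values == 1.0, axis=1)
    f = 1.0 - het / n_obs
    return pd.Series(f, index=pd.Index(g.individual_ids, name="id"), name="f")


def write_inbreeding(f: pd.Series, path) -> None:
    f.to_csv(path, sep="\t", header=True)


def impute_missing(g: GenotypeMatrix, freqs: np.ndarray) -> np.ndarray:
    """Replace missing entries by their expectation 2p (mean imputation).

    Used only when building relationship matrices; after centering by 2p an
    imputed entry contributes exactly zero.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (g.n_snps,):
        raise ValueError("frequency vector does not match SNP count")
    out = g.values.copy()
    miss = g.missing_mask
    out[miss] = np.broadcast_to(2.0 * freqs, out.shape)[miss]
    return out


def apply_qc(g: GenotypeMatrix, thresholds: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the four marker/individual filters in a fixed order.

    Order: individual call rate, SNP call rate, minor allele frequency,
    Hardy-Weinberg heterozygote deviation. Each removed SNP is attributed
    to exactly the first filter that catches it.
    """
    thr = thresholds or QCThresholds()
    n_ind_in, n_snp_in = g.n_individuals, g.n_snps

    obs = ~g.missing_mask
    ind_cr = obs.mean(axis=1)
    keep_ind = ind_cr >= thr.ind_call_rate
    g1 = g.subset(rows=np.where(keep_ind)[0])
    n_rm_ind = int((~keep_ind).sum())

    obs = ~g1.missing_mask
    snp_cr = obs.mean(axis=0)
    keep_cr = snp_cr >= thr.snp_call_rate
    n_rm_cr = int((~keep_cr).sum())
    g2 = g1.subset(cols=np.where(keep_cr)[0])

    p = allele_frequencies(g2)
    maf = np.minimum(p, 1.0 - p)
    keep_maf = maf >= thr.maf
    n_rm_maf = int((~keep_maf).sum())
    g3 = g2.subset(cols=np.where(keep_maf)[0])
    p = p[keep_maf]

    obs = ~g3.missing_mask
    het_freq = np.nansum(g3.values == 1.0, axis=0) / obs.sum(axis=0)
    expected = 2.0 * p * (1.0 - p)
    keep_hwe = np.abs(het_freq - expected) <= thr.hwe_het_deviation
    n_rm_hwe = int((~keep_hwe).sum())
    g4 = g3.subset(cols=np.where(keep_hwe)[0])

    report = QCReport(
        n_individuals_in=n_ind_in,
        n_individuals_out=g4.n_individuals,
        n_snps_in=n_snp_in,
        n_snps_out=g4.n_snps,
        removed_individual_call_rate=n_rm_ind,
        removed_snp_call_rate=n_rm_cr,
        removed_maf=n_rm_maf,
        removed_hwe=n_rm_hwe,
        thresholds=thr,
    )
    return g4, report
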