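"""Data model and I/O for genotypes, annotations, phenotypes and candidate lists.

Genotypes are stored as minor-allele counts for a panel of (typically inbred)
accessions: haploid-style 0/1 coding by default, with 0/1/2 supported for
diploid panels.  Missing calls are carried as NaN behind a mask.  Phenotypes
pass through a deterministic impute-then-normalize preparation before any
association testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from scipy import stats

logger = logging.getLogger(__name__)

SITE_CLASSES = ("intergenic", "intronic", "synonymous", "nonsynonymous")

ANNOTATION_COLUMNS = (
    "snp_id",
    "fragment_id",
    "gene_id",
    "site_class",
    "nonsense",
    "polyphen",
    "sift",
    "delta_score",
)


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


@dataclass
class GenotypeMatrix:
    """Sample x SNP minor-allele count matrix with a missing mask.

    ``calls`` is float so missing entries can be NaN; non-missing entries are
    integers in ``[0, ploidy]``.  SNP columns are oriented so the counted
    allele is the minor one (frequency <= 0.5).
    """

    samples: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    ploidy: int = 1
    chrom: list[str] | None = None
    pos: np.ndarray | None = None
    rejected_sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        n, m = self.calls.shape
        if len(self.samples) != n or len(self.snp_ids) != m:
            raise ValueError("calls shape does not match sample/SNP labels")
        if n < 2 or m < 1:
            raise ValueError("need at least 2 samples and 1 SNP")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP identifiers")
        observed = self.calls[~np.isnan(self.calls)]
        if observed.size and (
            (observed < 0).any()
            or (observed > self.ploidy).any()
            or (observed != np.round(observed)).any()
        ):
            raise ValueError(f"calls must be integers in [0, {self.ploidy}] or missing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.calls)

    def mean_imputed(self) -> np.ndarray:
        """Calls with per-SNP mean substituted for missing entries.

        Used for kinship, PCA and regression designs only; never written back.
        """
        out = self.calls.copy()
        col_mean = np.nanmean(out, axis=0)
        idx = np.where(np.isnan(out))
        out[idx] = col_mean[idx[1]]
        return out


def _orient_minor(calls: np.ndarray, ploidy: int) -> np.ndarray:
    """Flip columns whose counted-allele frequency exceeds 0.5."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=0) / ploidy
    flip = freq > 0.5
    calls = calls.copy()
    calls[:, flip] = ploidy - calls[:, flip]
    return calls


def read_genotypes(path: str | Path, fmt: str = "tsv", ploidy: int = 1) -> GenotypeMatrix:
    """Load genotypes from a TSV matrix or a VCF.

    TSV layout: first column sample id, header row SNP ids, cells 0/1/2/NA.
    VCF: biallelic records only; multi-allelic sites are skipped and recorded
    in ``rejected_sites``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        return _read_genotypes_tsv(path, ploidy)
    if fmt == "vcf":
        return _read_genotypes_vcf(path, ploidy)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotypes_tsv(path: Path, ploidy: int) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise GenotypeParseError(f"{path}: no SNP columns")
    calls = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            cell = str(cell).strip()
            if cell in ("NA", "", ".", "nan"):
                continue
            try:
                calls[i, j] = int(cell)
            except ValueError as exc:
                raise GenotypeParseError(
                    f"{path}: line {i + 2}, column {col!r}: bad call {cell!r}"
                ) from exc
    calls = _orient_minor(calls, ploidy)
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        snp_ids=[str(c) for c in df.columns],
        calls=calls,
        ploidy=ploidy,
    )


def _read_genotypes_vcf(path: Path, ploidy: int) -> GenotypeMatrix:
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    snp_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    rejected: list[str] = []
    for rec in vf:
        rid = rec.id or f"{rec.chrom}:{rec.pos}"
        if rec.alts is None or len(rec.alts) != 1:
            rejected.append(rid)
            logger.info("rejected non-biallelic site %s", rid)
            continue
        col = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or all(a is None for a in gt):
                continue
            alleles = [a for a in gt if a is not None]
            if ploidy == 1:
                # haploid coding of an inbred diploid call: 0/0 -> 0, 1/1 -> 1
                col[i] = round(sum(alleles) / len(alleles))
            else:
                col[i] = float(sum(alleles))
        snp_ids.append(rid)
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        columns.append(col)
    vf.close()
    if not columns:
        raise GenotypeParseError(f"{path}: no usable biallelic records")
    calls = _orient_minor(np.column_stack(columns), ploidy)
    return GenotypeMatrix(
        samples=samples,
        snp_ids=snp_ids,
        calls=calls,
        ploidy=ploidy,
        chrom=chroms,
        pos=np.asarray(positions),
        rejected_sites=rejected,
    )


def compute_maf(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor-allele frequency over non-missing calls.

    After minor-allele orientation this is simply the mean call over ploidy,
    folded into [0, 0.5].
    """
    n_obs = (~geno.missing_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [geno.snp_ids[j] for j in np.where(n_obs == 0)[0]]
        raise ValueError(f"all-missing SNP(s): {bad}")
    freq = np.nanmean(geno.calls, axis=0) / geno.ploidy
    return np.minimum(freq, 1.0 - freq)


def classify_rarity(maf: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Label SNPs 'rare' (0 < MAF < threshold, strict), 'common', or 'monomorphic'."""
    maf = np.asarray(maf, dtype=float)
    if ((maf < 0) | (maf > 0.5)).any():
        raise ValueError("MAF values must lie in [0, 0.5]")
    out = np.where(maf == 0.0, "monomorphic", np.where(maf < threshold, "rare", "common"))
    return out.astype(object)


@dataclass
class PhenotypeTable:
    """Sample x trait phenotype values with missing mask and processing state."""

    samples: list[str]
    traits: list[str]
    values: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.traits)):
            raise ValueError("values shape does not match sample/trait labels")
        if self.state not in ("raw", "imputed", "normalized"):
            raise ValueError(f"bad state {self.state!r}")
        if self.state in ("imputed", "normalized") and np.isnan(self.values).any():
            raise ValueError(f"state {self.state!r} forbids missing values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.traits)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """TSV: first column sample id, header trait names, NA for missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PhenotypeTable(
        samples=[str(s) for s in df.index],
        traits=[str(t) for t in df.columns],
        values=df.to_numpy(dtype=float),
    )


def impute_phenotypes(pheno: PhenotypeTable, k_neighbors: int = 3) -> PhenotypeTable:
    """Fill missing cells by correlation-weighted nearest-trait prediction.

    Each trait is standardized over its observed entries; a missing cell is
    predicted from the sample's k most correlated observed traits (nearest by
    absolute trait-trait Pearson correlation over complete pairs), combining
    signed standardized donor values with |r| weights, then mapped back to the
    target trait's scale.  Deterministic given inputs.
    """
    vals = pheno.values.copy()
    n, t = vals.shape
    obs = ~np.isnan(vals)
    if (obs.sum(axis=0) < 2).any():
        bad = [pheno.traits[j] for j in np.where(obs.sum(axis=0) < 2)[0]]
        raise ValueError(f"trait(s) with fewer than 2 observations: {bad}")
    if (obs.sum(axis=1) == 0).any():
        bad = [pheno.samples[i] for i in np.where(obs.sum(axis=1) == 0)[0]]
        raise ValueError(f"sample(s) with all traits missing: {bad}")
    if not np.isnan(vals).any():
        return PhenotypeTable(pheno.samples, pheno.traits, vals, state="imputed")

    logger.info("imputing %d missing phenotype cells (k-nearest-trait stand-in)",
                int(np.isnan(vals).sum()))
    mean = np.nanmean(vals, axis=0)
    std = np.nanstd(vals, axis=0, ddof=0)
    std = np.where(std == 0, 1.0, std)
    z = (vals - mean) / std
    corr = pd.DataFrame(vals).corr(min_periods=2).to_numpy()
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)

    out = vals.copy()
    for i in range(n):
        for j in range(t):
            if not np.isnan(vals[i, j]):
                continue
            donors = [jj for jj in range(t) if obs[i, jj]]
            donors.sort(key=lambda jj: (-abs(corr[j, jj]), jj))
            donors = donors[:k_neighbors]
            w = np.array([abs(corr[j, jj]) for jj in donors])
            if w.sum() == 0:
                out[i, j] = mean[j]
                continue
            zhat = sum(
                abs(corr[j, jj]) * np.sign(corr[j, jj]) * z[i, jj] for jj in donors
            ) / w.sum()
            out[i, j] = mean[j] + std[j] * zhat
    return PhenotypeTable(pheno.samples, pheno.traits, out, state="imputed")


def normalize_phenotypes(pheno: PhenotypeTable) -> PhenotypeTable:
    """Per-trait rank-based inverse-normal transform (Blom offset 3/8, midranks)."""
    vals = pheno.values
    if np.isnan(vals).any():
        raise ValueError("normalize requires complete data; impute first")
    n = vals.shape[0]
    out = np.empty_like(vals)
    for j, trait in enumerate(pheno.traits):
        col = vals[:, j]
        if np.ptp(col) == 0:
            raise ValueError(f"constant trait {trait!r} cannot be normalized")
        ranks = stats.rankdata(col, method="average")
        out[:, j] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return PhenotypeTable(pheno.samples, pheno.traits, out, state="normalized")


@dataclass
class CandidateGeneList:
    """A curated, trait-relevant a priori candidate gene set."""

    genes: set[str]
    source: str = ""

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def read_candidate_list(path: str | Path, source: str = "") -> CandidateGeneList:
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g:
                genes.add(g)
    return CandidateGeneList(genes=genes, source=source or str(path))


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Load and validate the per-SNP annotation table."""
    df = pd.read_csv(
        path, sep="\t", dtype={"snp_id": str, "fragment_id": str, "gene_id": str}
    )
    return validate_annotations(df)


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    bad_class = set(df["site_class"].dropna()) - set(SITE_CLASSES)
    if bad_class:
        raise ValueError(f"unknown site_class values: {sorted(bad_class)}")
    df = df.copy()
    df["polyphen"] = df["polyphen"].fillna("none")
    df["sift"] = df["sift"].fillna("none")
    df["nonsense"] = df["nonsense"].astype(bool)
    nonsyn = df["site_class"] == "nonsynonymous"
    scored = (df["polyphen"] != "none") | (df["sift"] != "none")
    if (scored & ~nonsyn).any():
        bad = df.loc[scored & ~nonsyn, "snp_id"].tolist()
        raise ValueError(f"prediction categories on non-nonsynonymous SNPs: {bad}")
    return df
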