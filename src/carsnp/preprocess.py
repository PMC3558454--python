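"""GWAS preprocessing: recoding, filtering and response residualization.

The pipeline mirrors standard practice for exome-style association panels:

1. recode biallelic genotypes additively as minor-allele counts 0/1/2,
2. standardize columns to mean 0 / unit variance,
3. drop exact duplicate SNP columns (identical integer vectors),
4. keep only non-synonymous SNPs per the annotation,
5. regress non-genetic covariates out of the phenotype and standardize the
   residuals.

Missing genotypes are a hard error throughout — no imputation is attempted.
Readers are provided for tab-delimited genotype/phenotype/annotation tables
and for the PLINK ``.raw`` additive export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import StandardizedMatrix, standardize_columns

__all__ = [
    "PhenotypeVector",
    "recode_additive",
    "drop_duplicate_snps",
    "filter_nonsynonymous",
    "residualize_response",
    "preprocess_genotypes",
    "read_genotype_tsv",
    "read_plink_raw",
    "read_annotation",
    "read_phenotype",
]


@dataclass
class PhenotypeVector:
    """Phenotype values with optional covariates, keyed to the genotype rows."""

    values: np.ndarray
    covariates: np.ndarray | None = None
    id: str = "phenotype"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("phenotype must be a vector")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=np.float64)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != self.values.size:
                raise ValueError("covariate rows must match phenotype length")

    @property
    def n(self) -> int:
        return self.values.size


def recode_additive(raw_genotypes, snp_ids=None) -> tuple[np.ndarray, np.ndarray]:
    """Recode genotypes as minor-allele counts in {0, 1, 2}.

    Accepts either a numeric dosage matrix with entries in {0, 1, 2} or a
    matrix of allele-pair strings such as ``"AA"``, ``"AG"``, ``"A/G"``.  The
    minor allele is determined from the sample: if the counted allele has
    frequency above 0.5 the column is flipped (x -> 2 - x) so that 2 always
    counts minor-allele copies.

    Returns the int8 matrix and the SNP id array.  Sites with more than two
    alleles or any missing call raise ``ValueError``.
    """
    if isinstance(raw_genotypes, pd.DataFrame):
        if snp_ids is None:
            snp_ids = raw_genotypes.columns.to_numpy()
        raw_genotypes = raw_genotypes.to_numpy()
    arr = np.asarray(raw_genotypes)
    if arr.ndim != 2:
        raise ValueError("expected a samples x SNPs matrix")
    n, d = arr.shape
    if snp_ids is None:
        snp_ids = np.array([f"snp{i:05d}" for i in range(1, d + 1)])
    snp_ids = np.asarray(snp_ids)

    if arr.dtype.kind in "iuf":
        values = arr.astype(np.float64)
        if np.isnan(values).any():
            raise ValueError("missing genotype calls are not allowed")
        if not np.isin(values, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosage entries must be 0, 1 or 2")
        coded = values.astype(np.int8)
    else:
        coded = np.empty((n, d), dtype=np.int8)
        for j in range(d):
            col = arr[:, j]
            pairs = []
            for entry in col:
                s = str(entry).replace("/", "").replace("|", "").strip()
                if len(s) != 2 or any(c in ".0N" for c in s):
                    raise ValueError(
                        f"SNP {snp_ids[j]}: malformed or missing genotype {entry!r}"
                    )
                pairs.append((s[0], s[1]))
            alleles = sorted({a for pair in pairs for a in pair})
            if len(alleles) > 2:
                raise ValueError(
                    f"SNP {snp_ids[j]}: more than two alleles ({', '.join(alleles)})"
                )
            counted = alleles[-1]  # count copies of the lexically later allele
            coded[:, j] = [sum(a == counted for a in pair) for pair in pairs]

    # flip columns whose counted allele is actually the major one
    freq = coded.mean(axis=0) / 2.0
    flip = freq > 0.5
    coded[:, flip] = 2 - coded[:, flip]
    return coded, snp_ids


def drop_duplicate_snps(
    x: np.ndarray, ids
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Remove exactly duplicated columns, keeping the first occurrence.

    Duplicates are detected by exact integer equality of the coded genotype
    vectors.  Returns (matrix, kept ids, dropped ids) with input order
    preserved among kept columns.
    """
    x = np.asarray(x)
    ids = np.asarray(ids)
    seen: dict[bytes, int] = {}
    keep: list[int] = []
    dropped: list[int] = []
    for j in range(x.shape[1]):
        key = x[:, j].tobytes()
        if key in seen:
            dropped.append(j)
        else:
            seen[key] = j
            keep.append(j)
    return x[:, keep], ids[keep], ids[dropped]


def filter_nonsynonymous(
    x: np.ndarray, ids, annotation: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Keep only columns annotated as non-synonymous.

    ``annotation`` must contain columns ``snp_id`` and ``synonymous`` (bool or
    0/1) covering every id; unannotated ids raise, as does an empty result.
    """
    x = np.asarray(x)
    ids = np.asarray(ids)
    ann = annotation.set_index("snp_id")["synonymous"]
    missing = [str(i) for i in ids if i not in ann.index]
    if missing:
        raise ValueError(f"unannotated SNP id(s): {', '.join(missing[:10])}")
    synonymous = ann.loc[ids].astype(bool).to_numpy()
    keep = ~synonymous
    if not keep.any():
        raise ValueError("no predictors remain after the synonymous filter")
    return x[:, keep], ids[keep]


def residualize_response(y: PhenotypeVector) -> np.ndarray:
    """Regress covariates out of the phenotype and standardize the residuals.

    Ordinary least squares of y on (intercept + covariates); residuals are
    centered by construction and scaled to unit sample variance (ddof=1).
    Without covariates this reduces to standardizing y.
    """
    values = y.values
    n = values.size
    if y.covariates is None:
        resid = values - values.mean()
    else:
        c = y.covariates.shape[1]
        if n <= c + 1:
            raise ValueError("need more samples than covariates plus intercept")
        design = np.column_stack([np.ones(n), y.covariates])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        resid = values - design @ coef
    sd = resid.std(ddof=1)
    if sd <= 1e-12 * max(1.0, np.abs(values).max()):
        raise ValueError("response fully explained by covariates (zero residual variance)")
    return resid / sd


def preprocess_genotypes(
    raw_genotypes, snp_ids=None, annotation: pd.DataFrame | None = None
) -> tuple[StandardizedMatrix, dict]:
    """Full genotype pipeline: recode, standardize, deduplicate, filter.

    Returns the standardized predictor matrix and a stage log recording the
    column count after every step.  Duplicate detection always runs on the
    integer-coded matrix; the corresponding standardized columns are dropped.
    """
    coded, ids = recode_additive(raw_genotypes, snp_ids)
    log = {"input": int(coded.shape[1])}
    std = standardize_columns(coded, ids)
    log["standardized"] = std.d
    coded, kept, dropped = drop_duplicate_snps(coded, ids)
    values = std.values[:, np.isin(ids, kept)]
    log["deduplicated"] = int(values.shape[1])
    log["duplicates_dropped"] = int(dropped.size)
    ids = kept
    if annotation is not None:
        mask_source, ids = filter_nonsynonymous(coded, ids, annotation)
        values = values[:, np.isin(kept, ids)]
        log["nonsynonymous"] = int(values.shape[1])
    return StandardizedMatrix(values, ids), log


# ---------------------------------------------------------------------------
# file readers (tab-delimited dialect: header row, '#' comment lines)
# ---------------------------------------------------------------------------

def read_genotype_tsv(path) -> pd.DataFrame:
    """Samples x SNPs genotype table: first column sample id, header SNP ids."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if frame.shape[1] < 1:
        raise ValueError(f"{path}: no SNP columns found")
    return frame


def read_plink_raw(path, strip_allele: bool = True) -> pd.DataFrame:
    """PLINK ``.raw`` additive export: FID IID PAT MAT SEX PHENOTYPE + dosages.

    Returns a samples x SNPs dosage DataFrame indexed by IID.  The counted
    allele suffix (``_A``) is stripped from SNP ids unless ``strip_allele``
    is False.  Missing dosages (NA) raise.
    """
    frame = pd.read_csv(path, sep=r"\s+")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(frame.columns[:6]) != meta_cols:
        raise ValueError(f"{path}: not a PLINK .raw file (header mismatch)")
    geno = frame.drop(columns=meta_cols[:1] + meta_cols[2:]).set_index("IID")
    if geno.isna().any().any():
        raise ValueError(f"{path}: missing genotype dosages are not allowed")
    if strip_allele:
        geno.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
    return geno


def read_annotation(path) -> pd.DataFrame:
    """SNP annotation table with at least snp_id, gene_id, synonymous."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"snp_id", "gene_id", "synonymous"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation column(s) {sorted(missing)}")
    if frame["snp_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate snp_id entries")
    return frame


def read_phenotype(path, value_col: str | None = None) -> pd.DataFrame:
    """Phenotype/covariate table keyed by sample id (first column)."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if value_col is not None and value_col not in frame.columns:
        raise ValueError(f"{path}: phenotype column {value_col!r} not found")
    return frame
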