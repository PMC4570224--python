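"""Genotype matrices: synthetic SNP simulation, real-data ingestion, standardization.

Synthetic genomes follow the standard GWAS-simulation recipe: each locus gets a
population minor-allele frequency drawn uniformly from the open interval
(0.05, 0.5), and each diploid dosage (0, 1 or 2 copies of the minor allele) is
the sum of two independent Bernoulli(maf) draws — i.e. Hardy–Weinberg
equilibrium with unlinked loci and i.i.d. individuals.  A continuous mode with
i.i.d. standard-normal entries (the canonical compressed-sensing ensemble) is
provided for studying the method outside the discrete-genotype setting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "sample_mafs",
    "generate_snp_matrix",
    "generate_continuous_matrix",
    "load_genotypes",
    "standardize",
    "unstandardize",
]

MAF_LOW = 0.05
MAF_HIGH = 0.5


@dataclass
class GenotypeMatrix:
    """An n (individuals) x p (loci) dosage matrix with provenance metadata.

    ``dosages`` holds allele counts in {0, 1, 2} for the SNP modes, or
    real values in continuous mode.  ``maf`` carries the population
    minor-allele frequency per locus for synthetic SNP matrices (empirical
    frequencies for ingested data).
    """

    dosages: np.ndarray
    mode: str  # "snp-synthetic" | "snp-real" | "continuous"
    maf: np.ndarray | None = None
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (individuals x loci) array")
        if self.mode not in ("snp-synthetic", "snp-real", "continuous"):
            raise ValueError(f"unknown genotype mode {self.mode!r}")
        if not self.locus_ids:
            self.locus_ids = [f"L{i}" for i in range(self.p)]
        if len(self.locus_ids) != self.p:
            raise ValueError("locus_ids length does not match locus count")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Write the dosage table (individuals x loci, header = locus ids)."""
        df = pd.DataFrame(self.dosages, columns=self.locus_ids)
        df.to_csv(path, sep="\t", index=False)

    def maf_to_tsv(self, path: str | os.PathLike) -> None:
        if self.maf is None:
            raise ValueError("no MAF metadata on this matrix")
        pd.DataFrame({"locus_id": self.locus_ids, "maf": self.maf}).to_csv(
            path, sep="\t", index=False
        )


def sample_mafs(p: int, seed: int | np.random.Generator) -> np.ndarray:
    """Draw p population minor-allele frequencies uniformly from (0.05, 0.5).

    The interval is open at both ends; draws landing exactly on a boundary at
    floating-point precision are rejected and redrawn.
    """
    if p < 0:
        raise ValueError(f"p must be non-negative, got {p}")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(MAF_LOW, MAF_HIGH, size=p)
    # np.uniform is half-open [low, high); reject exact boundary hits.
    bad = maf <= MAF_LOW
    while bad.any():
        maf[bad] = rng.uniform(MAF_LOW, MAF_HIGH, size=int(bad.sum()))
        bad = maf <= MAF_LOW
    return maf


def generate_snp_matrix(
    n: int, p: int, maf: np.ndarray, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Simulate an n x p diploid dosage matrix under Hardy–Weinberg sampling.

    Entry (a, i) ~ Binomial(2, maf_i), independent across individuals and loci.
    """
    maf = np.asarray(maf, dtype=float)
    if maf.shape != (p,):
        raise ValueError(f"maf has length {maf.size}, expected p={p}")
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("all maf values must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, maf, size=(n, p)).astype(np.int8)
    return GenotypeMatrix(dosages=dosages, mode="snp-synthetic", maf=maf.copy())


def generate_continuous_matrix(
    n: int,
    p: int,
    seed: int | np.random.Generator,
    maf: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Simulate an n x p sensing matrix with continuous dosage-like entries.

    Entry (a, i) ~ Gamma with the mean 2*maf_i and variance 2*maf_i*(1-maf_i)
    of the diploid dosage at that locus — a continuous stand-in for SNP data
    that keeps dosages non-negative and right-skewed.  (A symmetric ensemble
    such as i.i.d. Gaussians would make purely quadratic effects marginally
    invisible — E[g^3] = 0 — turning every such locus into a model zero;
    matching the dosage skew preserves the intended contrast that continuous
    entries *reduce* the model-zero rate.)  ``maf`` defaults to a fresh
    uniform (0.05, 0.5) draw from the same seed stream.
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be at least 1 in continuous mode")
    rng = np.random.default_rng(seed)
    if maf is None:
        maf = sample_mafs(p, rng)
    maf = np.asarray(maf, dtype=float)
    if maf.shape != (p,):
        raise ValueError(f"maf has length {maf.size}, expected p={p}")
    shape = 2.0 * maf / (1.0 - maf)  # mean^2 / var
    scale = 1.0 - maf  # var / mean
    dosages = rng.gamma(shape, scale, size=(n, p))
    return GenotypeMatrix(dosages=dosages, mode="continuous", maf=maf.copy())


def _read_vcf(path: str) -> tuple[np.ndarray, list[str]]:
    from cyvcf2 import VCF

    dosage_cols: list[np.ndarray] = []
    ids: list[str] = []
    vcf = VCF(path)
    n_dropped_missing = 0
    n_dropped_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:  # biallelic only
            n_dropped_multi += 1
            continue
        col = np.empty(len(variant.genotypes), dtype=np.int8)
        ok = True
        for a, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]  # trailing element is the phased flag
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid record at {variant.CHROM}:{variant.POS}"
                )
            if any(al < 0 for al in alleles):
                ok = False
                break
            col[a] = alleles[0] + alleles[1]
        if not ok:
            n_dropped_missing += 1
            continue
        dosage_cols.append(col)
        vid = variant.ID if variant.ID not in (None, ".") else (
            f"{variant.CHROM}:{variant.POS}"
        )
        ids.append(vid)
    if n_dropped_missing or n_dropped_multi:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d loci with missing genotypes, %d non-biallelic loci",
            n_dropped_missing,
            n_dropped_multi,
        )
    if not dosage_cols:
        raise ValueError(f"no eligible biallelic loci found in {path}")
    return np.column_stack(dosage_cols), ids


def _read_table(path: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep=None, engine="python")
    if df.isna().any().any():
        n_before = df.shape[1]
        df = df.dropna(axis=1)
        import logging

        logging.getLogger(__name__).info(
            "dropped %d loci with missing dosages", n_before - df.shape[1]
        )
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{path} is not a numeric dosage table")
    return arr, [str(c) for c in df.columns]


def load_genotypes(
    path: str | os.PathLike,
    p_select: int,
    seed: int | np.random.Generator,
    min_maf: float | None = None,
) -> GenotypeMatrix:
    """Load real genotypes (VCF or delimited dosage table) and subsample loci.

    ``p_select`` loci are chosen uniformly at random without replacement from
    those passing QC: biallelic, no missing genotypes (loci with any
    missingness are dropped), and — optionally — empirical MAF >= ``min_maf``.
    VCF dosages count ALT alleles; tables are read as individuals x loci with
    a header row of locus IDs.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"genotype file not found: {path}")
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        dosages, ids = _read_vcf(path)
    else:
        dosages, ids = _read_table(path)

    freq = dosages.mean(axis=0) / 2.0
    emp_maf = np.minimum(freq, 1.0 - freq)
    if min_maf is not None:
        keep = emp_maf >= min_maf
        dosages, emp_maf = dosages[:, keep], emp_maf[keep]
        ids = [i for i, k in zip(ids, keep) if k]

    if p_select > dosages.shape[1]:
        raise ValueError(
            f"requested {p_select} loci but only {dosages.shape[1]} pass QC"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(dosages.shape[1], size=p_select, replace=False))
    return GenotypeMatrix(
        dosages=dosages[:, chosen],
        mode="snp-real",
        maf=emp_maf[chosen],
        locus_ids=[ids[i] for i in chosen],
    )


def standardize(
    gm: GenotypeMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize a genotype matrix to mean 0, variance 1.

    Returns ``(A, mean, scale)`` with ``A = (dosages - mean) / scale`` and
    ``scale = sqrt(population variance)`` (ddof=0, so each column of A has
    A_j . A_j == n exactly — the convention the coordinate-descent updates
    assume).  Monomorphic columns cannot be standardized and raise.
    """
    X = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    X = X.astype(np.float64, copy=False)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    zero = np.nonzero(scale == 0)[0]
    if zero.size:
        raise ValueError(
            f"monomorphic (zero-variance) column(s) at index {zero[:5].tolist()}"
            " cannot be standardized"
        )
    return (X - mean) / scale, mean, scale


def unstandardize(A: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    """Invert :func:`standardize`."""
    return A * scale + mean


def standardize_lenient(X: np.ndarray) -> np.ndarray:
    """Standardize columns, mapping monomorphic columns to all-zeros.

    Used on subsamples during the sample-size scan, where a rare allele can be
    absent from a small subsample; an all-zero column is inert in the fit.
    """
    X = np.asarray(X, dtype=np.float64)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    safe = np.where(scale == 0, 1.0, scale)
    A = (X - mean) / safe
    A[:, scale == 0] = 0.0
    return A
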