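"""Genotype ingestion, filtering, standardization and IBS kinship.

Genotypes come from fully selfing inbred lines, so every line carries a
single allele per site and calls are coded 0/1 (haploid-equivalent).
Relatedness between lines is summarized by identity-by-state (IBS): the
fraction of genotyped sites at which two lines carry the same allele.
The resulting kinship matrix parameterizes the polygenic random effect
``u ~ N(0, sigma_g^2 K)`` used throughout the mixed-model stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SNP",
    "GenotypeMatrix",
    "KinshipMatrix",
    "GenotypeError",
    "ParseError",
    "EmptyResultError",
    "DegenerateInputError",
    "load_genotypes",
    "write_genotypes",
    "maf_filter",
    "standardize",
    "standardize_columns",
    "impute_missing",
    "ibs_kinship",
    "local_window",
    "load_kinship",
    "write_kinship",
]


class GenotypeError(ValueError):
    """Base class for genotype-layer failures."""


class ParseError(GenotypeError):
    """A genotype file could not be parsed."""


class EmptyResultError(GenotypeError):
    """An operation removed every SNP (or found none in a window)."""


class DegenerateInputError(GenotypeError):
    """Input is constant or otherwise carries no usable variation."""


class SNP(NamedTuple):
    chrom: str
    pos: int  # 1-based bp
    id: str


@dataclass
class GenotypeMatrix:
    """n lines x p biallelic SNPs, calls in {0, 1} with NaN for missing.

    Columns are sorted by (chromosome, position) on construction.
    """

    lines: list[str]
    snps: list[SNP]
    calls: np.ndarray  # float64, shape (n, p)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        n, p = self.calls.shape
        if n < 2 or p < 1:
            raise GenotypeError(f"need n >= 2 lines and p >= 1 SNPs, got {n} x {p}")
        if len(self.lines) != n or len(self.snps) != p:
            raise GenotypeError("lines/snps lengths do not match call matrix shape")
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and not np.all((finite == 0) | (finite == 1)):
            raise GenotypeError("non-missing calls must be 0 or 1")
        order = sorted(range(p), key=lambda j: (self.snps[j].chrom, self.snps[j].pos))
        if order != list(range(p)):
            self.snps = [self.snps[j] for j in order]
            self.calls = self.calls[:, order]

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of allele 1 among non-missing calls."""
        return np.nanmean(self.calls, axis=0)

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def take_lines(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        if len(idx) < 2:
            raise GenotypeError("need at least 2 lines")
        return GenotypeMatrix(
            lines=[self.lines[i] for i in idx],
            snps=list(self.snps),
            calls=self.calls[idx, :].copy(),
        )

    def take_snps(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        if not idx:
            raise EmptyResultError("SNP selection is empty")
        return GenotypeMatrix(
            lines=list(self.lines),
            snps=[self.snps[j] for j in idx],
            calls=self.calls[:, idx].copy(),
        )


@dataclass
class KinshipMatrix:
    """Symmetric IBS relatedness with unit diagonal."""

    lines: list[str]
    values: np.ndarray  # (n, n)
    snp_count: int = 0
    jitter: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.lines)
        if self.values.shape != (n, n):
            raise GenotypeError("kinship shape does not match line count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise GenotypeError("kinship matrix is not symmetric")

    @property
    def n_lines(self) -> int:
        return len(self.lines)


def _parse_matrix_tsv(path: str) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse genotype TSV {path!r}: {exc}") from exc
    snps = []
    for col in df.columns:
        try:
            chrom, pos = str(col).rsplit(":", 1)
            snps.append(SNP(chrom, int(pos), str(col)))
        except ValueError as exc:
            raise ParseError(
                f"genotype TSV column {col!r} is not of the form chrom:pos"
            ) from exc
    calls = df.to_numpy(dtype=float)
    return GenotypeMatrix(lines=[str(i) for i in df.index], snps=snps, calls=calls)


def _parse_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    lines = list(vcf.samples)
    snps: list[SNP] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    n_het = 0
    for variant in vcf:
        alts = variant.ALT
        if len(alts) != 1 or len(variant.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(variant.gt_types)  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        calls = np.full(gt.shape, np.nan)
        calls[gt == 0] = 0.0
        calls[gt == 3] = 1.0
        het = gt == 1
        if het.any():
            # inbred-line data: a het call is treated as missing, then imputed
            # to the column major allele below
            n_het += int(het.sum())
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        snps.append(SNP(str(variant.CHROM), int(variant.POS), snp_id))
        rows.append(calls)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    if not snps:
        raise ParseError(f"no biallelic SNP records in {path!r}")
    calls = np.column_stack(rows)
    if n_het:
        logger.info("set %d heterozygous calls missing (inbred lines expected)", n_het)
        freq = np.nanmean(calls, axis=0)
        major = (freq > 0.5).astype(float)
        nan_mask = np.isnan(calls)
        calls[nan_mask] = np.broadcast_to(major, calls.shape)[nan_mask]
    g = GenotypeMatrix(lines=lines, snps=snps, calls=calls)
    g.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return g


def load_genotypes(source: str, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from a VCF or the chrom:pos-header TSV dialect.

    ``format`` is ``"vcf"`` or ``"matrix-tsv"``; inferred from the file
    extension when omitted. Non-biallelic VCF records are skipped (count
    logged); heterozygous calls are imputed to the column major allele.
    """
    if format is None:
        s = str(source)
        format = "vcf" if s.endswith((".vcf", ".vcf.gz", ".bcf")) else "matrix-tsv"
    if format == "vcf":
        return _parse_vcf(str(source))
    if format == "matrix-tsv":
        return _parse_matrix_tsv(str(source))
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str) -> None:
    """Write the TSV dialect: header = chrom:pos ids, one row per line."""
    df = pd.DataFrame(
        g.calls,
        index=pd.Index(g.lines, name="line"),
        columns=[f"{s.chrom}:{s.pos}" for s in g.snps],
    )
    # keep integral calls integral in the text representation
    df.to_csv(path, sep="\t", float_format="%.6g")


def maf_filter(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Exclude SNPs with minor-allele frequency <= ``threshold``.

    Retention is strict (MAF > threshold), so at the conventional 0.1
    cutoff a SNP at MAF exactly 0.1 is removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    keep = np.flatnonzero(g.maf() > threshold)
    if keep.size == 0:
        raise EmptyResultError(f"no SNPs with MAF > {threshold}")
    return g.take_snps(keep)


def standardize(v: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Center and scale to unit variance (population SD, divisor n).

    With divisor-n scaling a standardized SNP column contributes exactly 1
    to the diagonal of its realized-relationship outer product, which keeps
    variance ratios interpretable across stages. Pass ``ddof=1`` for the
    sample-SD convention.
    """
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def standardize_columns(a: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Column-wise :func:`standardize`; constant columns raise."""
    a = np.asarray(a, dtype=float)
    sd = a.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise DegenerateInputError("matrix has constant columns")
    return (a - a.mean(axis=0)) / sd


def impute_missing(g: GenotypeMatrix, max_missing: float = 0.1) -> GenotypeMatrix:
    """Drop SNPs with > ``max_missing`` fraction missing, mean-impute the rest."""
    miss = np.isnan(g.calls).mean(axis=0)
    keep = np.flatnonzero(miss <= max_missing)
    if keep.size == 0:
        raise EmptyResultError("all SNPs exceed the missingness limit")
    if keep.size < g.n_snps:
        logger.info("dropped %d SNPs with >%g%% missing", g.n_snps - keep.size, 100 * max_missing)
    calls = g.calls[:, keep].copy()
    col_mean = np.nanmean(calls, axis=0)
    nan_mask = np.isnan(calls)
    calls[nan_mask] = np.broadcast_to(col_mean, calls.shape)[nan_mask]
    # imputed calls may be fractional; bypass the {0,1} validity check
    gm = object.__new__(GenotypeMatrix)
    gm.lines = list(g.lines)
    gm.snps = [g.snps[j] for j in keep]
    gm.calls = calls
    return gm


def ibs_kinship(g: GenotypeMatrix, psd_jitter: float = 1e-8) -> KinshipMatrix:
    """IBS kinship: entry (i, j) = fraction of SNPs with matching alleles.

    Accepts mean-imputed (fractional) calls, for which the allele-sharing
    probability ``g_i g_j + (1-g_i)(1-g_j)`` is used per site. The diagonal
    is 1 by definition. If the smallest eigenvalue is negative (possible
    after imputation), ``psd_jitter * I`` is added once.
    """
    calls = g.calls
    if np.isnan(calls).any():
        raise GenotypeError("missing calls present; run impute_missing first")
    p = g.n_snps
    if p == 0:
        raise EmptyResultError("no SNPs to compute kinship from")
    G = calls
    share = G @ G.T + (1.0 - G) @ (1.0 - G).T
    K = share / p
    np.fill_diagonal(K, 1.0)
    K = (K + K.T) / 2.0
    jitter = 0.0
    w_min = np.linalg.eigvalsh(K)[0]
    if w_min < 0:
        jitter = psd_jitter
        K = K + jitter * np.eye(K.shape[0])
        np.fill_diagonal(K, 1.0)
    return KinshipMatrix(lines=list(g.lines), values=K, snp_count=p, jitter=jitter)


def local_window(
    g: GenotypeMatrix,
    gene: tuple[str, int, int],
    flank: int = 15_000,
) -> GenotypeMatrix:
    """SNPs within ``[start - flank, end + flank]`` (closed, 1-based) on the
    gene's chromosome — the local window used for cis variance components."""
    chrom, start, end = gene
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo, hi = start - flank, end + flank
    idx = [
        j
        for j, s in enumerate(g.snps)
        if s.chrom == str(chrom) and lo <= s.pos <= hi
    ]
    if not idx:
        raise EmptyResultError(f"no SNPs in window {chrom}:{lo}-{hi}")
    return g.take_snps(idx)


def write_kinship(k: KinshipMatrix, path: str) -> None:
    pd.DataFrame(k.values, index=k.lines, columns=k.lines).to_csv(path, sep="\t")


def load_kinship(path: str) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError("kinship TSV row and column labels differ")
    return KinshipMatrix(lines=[str(i) for i in df.index], values=df.to_numpy(dtype=float))
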