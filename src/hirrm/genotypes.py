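"""SNP genotypes: PLINK bed/bim/fam I/O, marker QC and the genomic
relationship matrix.

Genotypes are held as counts of the A1 allele (0, 1, 2; NaN for missing) in
an n-individuals x m-markers array.  The genomic relationship matrix uses
the standardized cross-product K = W W' / m, where W is the count matrix
with each column centred by twice the allele frequency and scaled by
sqrt(2 p (1-p)); missing entries are mean-imputed per marker beforehand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenotypeMatrix", "Kinship", "read_plink", "write_plink",
           "filter_markers", "compute_grm"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major v1


@dataclass
class GenotypeMatrix:
    """Allele-count matrix with marker and individual metadata.

    ``genotypes``: float array, n x m, values in {0, 1, 2, NaN}.
    ``markers``: DataFrame with columns chrom, snp, cm, pos, a1, a2.
    ``ids``: individual identifiers, row-aligned.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-d")
        n, m = self.genotypes.shape
        if len(self.ids) != n or len(self.markers) != m:
            raise ValueError("genotype dimensions inconsistent with metadata")
        if (self.markers["pos"] < 0).any():
            raise ValueError("marker positions must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted (A1) allele per marker, from non-missing
        calls; NaN for all-missing markers."""
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.genotypes, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.genotypes).mean(axis=0)

    def imputed(self) -> np.ndarray:
        """Genotypes with missing entries replaced by the per-marker mean."""
        g = self.genotypes.copy()
        nan_mask = np.isnan(g)
        if nan_mask.any():
            means = 2.0 * self.allele_freq()
            means = np.where(np.isnan(means), 0.0, means)
            g[nan_mask] = np.broadcast_to(means, g.shape)[nan_mask]
        return g


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triplet (SNP-major .bed, v1).

    Returns counts of the A1 allele, individuals ordered as in the .fam file.
    """
    prefix = Path(prefix)
    bed_path, bim_path, fam_path = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(p)
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{bed_path}: invalid .bed magic bytes (expect SNP-major v1)")
    bytes_per_marker = (n + 3) // 4
    body = raw[3:]
    if body.size != m * bytes_per_marker:
        raise ValueError(
            f"{bed_path}: size {body.size} bytes inconsistent with "
            f"{n} individuals x {m} markers"
        )
    codes = body.reshape(m, bytes_per_marker)
    # unpack the four 2-bit fields of each byte (individual j is bits 2*(j%4))
    geno = np.empty((m, bytes_per_marker * 4), dtype=np.uint8)
    for j in range(4):
        geno[:, j::4] = (codes >> (2 * j)) & 0b11
    geno = geno[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    counts = lut[geno].T  # n x m
    return GenotypeMatrix(counts, bim, fam["iid"].tolist())


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a GenotypeMatrix as a PLINK .bed/.bim/.fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = pd.DataFrame({
        "fid": g.ids, "iid": g.ids, "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    g.markers[["chrom", "snp", "cm", "pos", "a1", "a2"]].to_csv(
        prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    n, m = g.genotypes.shape
    # map counts back to 2-bit codes
    code = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    gt = g.genotypes.T
    code[gt == 2] = 0b00
    code[gt == 1] = 0b10
    code[gt == 0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.concatenate(
            [code, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    packed = np.zeros((m, code.shape[1] // 4), dtype=np.uint8)
    for j in range(4):
        packed |= code[:, j::4] << (2 * j)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def filter_markers(g: GenotypeMatrix, maf_min: float = 0.01,
                   missing_max: float = 0.1) -> GenotypeMatrix:
    """Retain markers with MAF >= maf_min and missing rate <= missing_max,
    preserving order."""
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    maf = g.maf()
    if maf_min == 0:
        keep_maf = np.ones(g.n_markers, dtype=bool)
    else:  # NaN MAF (all-missing marker) fails any positive threshold
        keep_maf = np.nan_to_num(maf, nan=-1.0) >= maf_min
    keep = keep_maf & (g.missing_rate() <= missing_max)
    logger.info("marker QC: %d of %d retained (MAF>=%g, missing<=%g)",
                int(keep.sum()), g.n_markers, maf_min, missing_max)
    return GenotypeMatrix(
        g.genotypes[:, keep],
        g.markers.loc[keep].reset_index(drop=True),
        list(g.ids),
    )


@dataclass
class Kinship:
    """Genomic relationship matrix with a cached spectral decomposition."""

    matrix: np.ndarray
    ids: list[str]
    _eig: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or len(self.ids) != n:
            raise ValueError("kinship must be square and id-aligned")
        if np.max(np.abs(self.matrix - self.matrix.T)) > 1e-10:
            raise ValueError("kinship matrix not symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def eigen(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues Sk (descending) and eigenvectors Uk with
        K = Uk diag(Sk) Uk'."""
        if self._eig is None:
            sk, uk = np.linalg.eigh(self.matrix)
            order = np.argsort(sk)[::-1]
            self._eig = (sk[order], uk[:, order])
        return self._eig

    def add_ridge(self, eps: float = 1e-6) -> "Kinship":
        return Kinship(self.matrix + eps * np.eye(self.n), list(self.ids))


def compute_grm(g: GenotypeMatrix) -> Kinship:
    """Standardized genomic relationship matrix K = W W' / m.

    Missing genotypes are mean-imputed per marker; columns are centred by
    2p and scaled by sqrt(2p(1-p)).  Monomorphic markers make the scaling
    degenerate and raise.  K is bent to positive semidefinite by flooring
    negative eigenvalues at zero when numerical noise produces any.
    """
    x = g.imputed()
    p = x.mean(axis=0) / 2.0
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        raise ValueError(
            f"{int(mono.sum())} monomorphic markers; filter before computing the GRM")
    if g.n_markers < 2:
        raise ValueError("need at least 2 polymorphic markers")
    w = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    k = (w @ w.T) / g.n_markers
    k = 0.5 * (k + k.T)
    evals, evecs = np.linalg.eigh(k)
    if evals.min() < 0:
        if evals.min() < -1e-8:
            logger.warning("GRM bent to PSD: smallest eigenvalue %.3g", evals.min())
        k = (evecs * np.maximum(evals, 0.0)) @ evecs.T
        k = 0.5 * (k + k.T)
    return Kinship(k, list(g.ids))
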