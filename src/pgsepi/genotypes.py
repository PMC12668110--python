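"""Dosage-matrix container and a block-LD synthetic genotype generator.

The container holds an individuals x variants matrix of minor-allele dosages
in [0, 2] together with per-variant metadata (chromosome, position, MAF,
imputation-quality proxy, missingness).  The generator produces genotypes
under a latent-Gaussian haplotype model: within an LD block the latent
variables of the two haplotypes are equicorrelated with correlation ``rho``,
and each variant's allele indicator is obtained by thresholding its latent
value at the Normal quantile of its allele frequency.  Blocks are
independent, so inter-block LD is zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with per-variant metadata.

    Attributes
    ----------
    dosages : ndarray, shape (n_individuals, n_variants)
        Minor-allele dosages in [0, 2]; ``nan`` encodes a missing genotype.
    chrom : ndarray of int
        Chromosome label per variant (1-based).
    pos : ndarray of int
        1-based position, strictly increasing within each chromosome.
    variant_id : ndarray of str
    maf : ndarray of float
        Minor allele frequency computed from mean-imputed dosages.
    info : ndarray of float
        Imputation-quality proxy in [0, 1].
    missing_rate : ndarray of float
        Fraction of missing dosages per variant.
    block : ndarray of int, optional
        LD-block label per variant (populated by the synthetic generator;
        absent for genotypes read from files).
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    variant_id: np.ndarray
    maf: np.ndarray
    info: np.ndarray
    missing_rate: np.ndarray
    block: np.ndarray | None = None
    _imputed: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos)
        self.variant_id = np.asarray(self.variant_id)
        self.maf = np.asarray(self.maf, dtype=float)
        self.info = np.asarray(self.info, dtype=float)
        self.missing_rate = np.asarray(self.missing_rate, dtype=float)
        n, m = self.dosages.shape
        for name in ("chrom", "pos", "variant_id", "maf", "info", "missing_rate"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} length does not match variant count {m}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with missing values replaced by the per-variant mean.

        Cached; mean imputation preserves the allele frequency and is the
        conventional treatment for regression scans on dosage data.
        """
        if self._imputed is None:
            d = self.dosages
            if np.isnan(d).any():
                d = d.copy()
                col_mean = np.nanmean(d, axis=0)
                idx = np.where(np.isnan(d))
                d[idx] = col_mean[idx[1]]
            self._imputed = d
        return self._imputed

    def computed_maf(self) -> np.ndarray:
        """Allele frequency of the stored (minor) allele from imputed dosages."""
        return self.imputed().mean(axis=0) / 2.0

    def subset_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            variant_id=self.variant_id[idx],
            maf=self.maf[idx],
            info=self.info[idx],
            missing_rate=self.missing_rate[idx],
            block=None if self.block is None else self.block[idx],
        )


def _block_lengths(n: int, mean_len: int, rng: np.random.Generator) -> np.ndarray:
    """Partition ``n`` variants into contiguous blocks of geometric length."""
    lengths = []
    left = n
    while left > 0:
        L = min(int(rng.geometric(1.0 / max(mean_len, 1))), left)
        lengths.append(L)
        left -= L
    return np.asarray(lengths)


def generate_genotypes(
    n_individuals: int,
    n_variants: int,
    n_chromosomes: int = 22,
    mean_block_length: int = 20,
    block_rho: float = 0.8,
    maf_bounds: tuple[float, float] = (0.001, 0.5),
    mean_spacing: int = 30_000,
    maf_dist: str = "uniform",
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a block-LD dosage matrix over labelled chromosomes.

    Each of the two haplotypes per individual is drawn from a latent-Gaussian
    block model: within a block, latent values share an equicorrelation
    ``block_rho``; the allele indicator is ``z < Phi^-1(maf)``.  Dosage is the
    sum of the two haplotypes, re-oriented so the stored allele is the minor
    one.  Positions are random walks with mean step ``mean_spacing``.

    Parameters
    ----------
    maf_dist : {"uniform", "loguniform"}
        Distribution of target allele frequencies over ``maf_bounds``.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if n_variants < n_chromosomes:
        raise ValueError("n_variants must be >= n_chromosomes")
    lo, hi = maf_bounds
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_bounds must lie within (0, 0.5], got {maf_bounds}")
    if not (0.0 <= block_rho < 1.0):
        raise ValueError("block_rho must be in [0, 1)")

    rng = np.random.default_rng(seed)
    if maf_dist not in ("uniform", "loguniform"):
        raise ValueError(f"unknown maf_dist {maf_dist!r}")

    # contiguous, nearly equal chromosome assignment
    counts = np.full(n_chromosomes, n_variants // n_chromosomes)
    counts[: n_variants % n_chromosomes] += 1
    chrom = np.repeat(np.arange(1, n_chromosomes + 1), counts)

    pos = np.empty(n_variants, dtype=np.int64)
    start = 0
    for c in range(n_chromosomes):
        mc = counts[c]
        steps = rng.integers(1, 2 * mean_spacing, size=mc)
        pos[start : start + mc] = np.cumsum(steps)
        start += mc

    n_hap = 2 * n_individuals
    dosages = np.empty((n_individuals, n_variants))
    target_maf = np.empty(n_variants)
    block_label = np.empty(n_variants, dtype=np.int64)
    sr, si = np.sqrt(block_rho), np.sqrt(1.0 - block_rho)

    start = 0
    next_block = 0
    for c in range(n_chromosomes):
        mc = counts[c]
        for L in _block_lengths(mc, mean_block_length, rng):
            block_label[start : start + L] = next_block
            next_block += 1
            # variants sharing a block share a haplotype history, so their
            # frequencies are similar: one base MAF per block, jittered
            if maf_dist == "uniform":
                base = rng.uniform(lo, hi)
            else:
                base = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            maf_block = np.clip(
                base * np.exp(rng.normal(0.0, 0.15, size=L)), lo, hi
            )
            target_maf[start : start + L] = maf_block
            shared = rng.standard_normal((n_hap, 1))
            z = sr * shared + si * rng.standard_normal((n_hap, L))
            alleles = (z < ndtri(maf_block)).astype(float)
            dosages[:, start : start + L] = alleles[:n_individuals] + alleles[n_individuals:]
            start += L

    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    maf = np.where(flip, 1.0 - freq, freq)

    variant_id = np.array(
        [f"snp{c}_{p}" for c, p in zip(chrom, pos)], dtype=object
    )
    return GenotypeMatrix(
        dosages=dosages,
        chrom=chrom,
        pos=pos,
        variant_id=variant_id,
        maf=maf,
        info=np.ones(n_variants),
        missing_rate=np.zeros(n_variants),
        block=block_label,
    )
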