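"""Genome layout: marker map and QTL panel.

The simulated genome mimics a commercial 50K-style porcine SNP chip: a fixed
number of autosomes, each carrying evenly spaced biallelic SNP markers plus a
sparse grid of evenly spaced biallelic QTL. QTL effect magnitudes follow a
gamma distribution (heavy right tail: a few large-effect loci, many small
ones) and are assigned a random sign so the trait has zero-mean additive
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import stream

__all__ = ["GenomeSpec", "Genome", "build_genome", "sample_qtl_effects"]


@dataclass(frozen=True)
class GenomeSpec:
    """Structural parameters of the simulated genome.

    Defaults describe an 18-autosome genome with 2834 SNPs and 17 QTL per
    1-Morgan chromosome (51,012 SNPs genome-wide) and gamma(0.4, 1.66)
    QTL effect magnitudes.
    """

    n_chromosomes: int = 18
    chrom_length: float = 1.0  # Morgans
    snps_per_chrom: int = 2834
    qtls_per_chrom: int = 17
    gamma_shape: float = 0.4
    gamma_scale: float = 1.66

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.snps_per_chrom <= 0 or self.qtls_per_chrom <= 0:
            raise ValueError("chromosome, SNP and QTL counts must all be positive")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive (Morgans)")
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValueError("gamma QTL-effect parameters must be positive")

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chrom

    @property
    def n_qtls(self) -> int:
        return self.n_chromosomes * self.qtls_per_chrom

    @property
    def n_loci(self) -> int:
        return self.n_snps + self.n_qtls


@dataclass
class Genome:
    """A concrete marker map plus QTL panel.

    Loci are stored in a single genome-wide order, sorted by chromosome and
    position; ``is_qtl`` separates the SNP panel from the QTL panel.
    ``qtl_effects`` are the raw (unscaled) signed additive effects in trait
    units per allele copy; trait calibration rescales them.
    """

    spec: GenomeSpec
    chrom: np.ndarray  # (n_loci,) int16, chromosome index 0-based
    pos: np.ndarray  # (n_loci,) float64, position within chromosome in Morgans
    is_qtl: np.ndarray  # (n_loci,) bool
    qtl_effects: np.ndarray  # (n_qtl,) float64, signed raw effects

    _chrom_slices: list = field(default=None, repr=False)

    def __post_init__(self) -> None:
        order_ok = True
        for c in range(self.spec.n_chromosomes):
            p = self.pos[self.chrom == c]
            if p.size and np.any(np.diff(p) <= 0):
                order_ok = False
        if not order_ok:
            raise ValueError("locus positions must be strictly increasing within chromosome")
        if not np.all(np.isfinite(self.qtl_effects)):
            raise ValueError("QTL effects must be finite")

    @property
    def n_loci(self) -> int:
        return self.chrom.size

    @property
    def snp_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def chrom_slices(self) -> list:
        """Per-chromosome ``(start, stop)`` into the genome-wide locus order."""
        if self._chrom_slices is None:
            bounds = np.searchsorted(self.chrom, np.arange(self.spec.n_chromosomes + 1))
            self._chrom_slices = [(int(bounds[c]), int(bounds[c + 1])) for c in range(self.spec.n_chromosomes)]
        return self._chrom_slices

    def qtl_dosage(self, haplotypes: np.ndarray) -> np.ndarray:
        """Allele dosage (0/1/2) at QTL for ``haplotypes`` of shape (n, 2, L)."""
        h = np.atleast_3d(haplotypes)
        return (h[:, 0, :] + h[:, 1, :])[:, self.qtl_index].astype(np.int64)

    def snp_dosage(self, haplotypes: np.ndarray) -> np.ndarray:
        """Allele dosage (0/1/2) at SNP markers for haplotypes of shape (n, 2, L)."""
        h = np.atleast_3d(haplotypes)
        return (h[:, 0, :] + h[:, 1, :])[:, self.snp_index].astype(np.uint8)


def sample_qtl_effects(
    n_qtl: int, shape: float, scale: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw signed QTL effects: gamma(shape, scale) magnitudes, random sign.

    Signs are + or - with equal probability, giving a zero-mean effect
    distribution; magnitudes have mean ``shape * scale``.
    """
    if n_qtl <= 0:
        raise ValueError("n_qtl must be positive")
    if shape <= 0 or scale <= 0:
        raise ValueError("gamma shape and scale must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "qtl_effects")
    magnitudes = rng.gamma(shape, scale, size=n_qtl)
    signs = rng.choice([-1.0, 1.0], size=n_qtl)
    return magnitudes * signs


def _even_positions(n: int, length: float) -> np.ndarray:
    """n positions evenly spaced across [0, length] including both ends."""
    if n == 1:
        return np.array([length / 2.0])
    return np.linspace(0.0, length, n)


def build_genome(spec: GenomeSpec, seed: int) -> Genome:
    """Lay out the marker map and sample the QTL panel.

    SNPs are evenly spaced along each chromosome; QTL sit on their own even
    grid, offset so they interleave between markers. If any QTL would
    coincide with a SNP, the QTL grid is shifted deterministically by half a
    SNP interval.
    """
    snp_pos = _even_positions(spec.snps_per_chrom, spec.chrom_length)
    # Mid-interval grid keeps QTL strictly interior and between markers.
    qtl_pos = (np.arange(spec.qtls_per_chrom) + 0.5) * spec.chrom_length / spec.qtls_per_chrom
    if np.min(np.abs(snp_pos[:, None] - qtl_pos[None, :])) < 1e-12:
        half_snp = spec.chrom_length / max(spec.snps_per_chrom - 1, 1) / 2.0
        qtl_pos = qtl_pos + half_snp
        qtl_pos = np.clip(qtl_pos, 0.0, spec.chrom_length - 1e-9)

    per_pos = np.concatenate([snp_pos, qtl_pos])
    per_qtl = np.concatenate(
        [np.zeros(spec.snps_per_chrom, bool), np.ones(spec.qtls_per_chrom, bool)]
    )
    order = np.argsort(per_pos, kind="stable")
    per_pos, per_qtl = per_pos[order], per_qtl[order]

    chrom = np.repeat(np.arange(spec.n_chromosomes, dtype=np.int16), per_pos.size)
    pos = np.tile(per_pos, spec.n_chromosomes)
    is_qtl = np.tile(per_qtl, spec.n_chromosomes)
    effects = sample_qtl_effects(spec.n_qtls, spec.gamma_shape, spec.gamma_scale, seed)
    return Genome(spec=spec, chrom=chrom, pos=pos, is_qtl=is_qtl, qtl_effects=effects)
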