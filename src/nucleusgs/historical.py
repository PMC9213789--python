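"""Historical Wright-Fisher population: linkage disequilibrium by drift.

A neutral, discrete-generation random-mating population is simulated forward
in time through a schedule of census sizes: a long constant phase, a
bottleneck, then a final random-mating expansion that produces the founder
set of the recent breeding herd. Drift through the bottleneck generates the
linkage disequilibrium between markers and QTL that genomic prediction
exploits; no mutation, selection or migration act during this phase.

All loci start segregating at allele frequency 0.5. Because drift fixes a
fraction of loci, the map is oversampled by a configurable multiplier and,
at the end, the configured number of still-segregating loci nearest to the
ideal even grid is kept per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeding import stream
from .genome import Genome, GenomeSpec, sample_qtl_effects
from .meiosis import meiose_batch

__all__ = ["HistoricalSchedule", "FounderSet", "run_historical"]


@dataclass(frozen=True)
class HistoricalSchedule:
    """Census trajectory of the historical population.

    ``phases`` is an ordered list of ``(n_generations, start_size, end_size)``
    with sizes interpolated linearly inside each phase. The default encodes
    1000 generations at census 3000 followed by a gradual decline to 400
    over 20 generations, after which a single random-mating expansion
    produces ``expansion_size`` founders of whom ``expansion_males`` are male.
    """

    phases: tuple = ((1000, 3000, 3000), (20, 3000, 400))
    expansion_size: int = 2050
    expansion_males: int = 50

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("schedule needs at least one phase")
        for n_gen, a, b in self.phases:
            if n_gen <= 0 or a < 2 or b < 2:
                raise ValueError("phase generations must be positive and sizes >= 2")
        if not 0 < self.expansion_males < self.expansion_size:
            raise ValueError("expansion_males must be between 0 and expansion_size")

    def sizes(self) -> np.ndarray:
        """Per-generation census across all phases (expansion excluded)."""
        out = []
        for n_gen, a, b in self.phases:
            out.append(np.linspace(a, b, n_gen + 1)[1:] if a != b else np.full(n_gen, a))
        return np.rint(np.concatenate(out)).astype(np.int64)


@dataclass
class FounderSet:
    """Founders of the recent herd: recombined haplotypes plus sexes."""

    genome: Genome
    haplotypes: np.ndarray  # (n, 2, n_loci) uint8
    sex: np.ndarray  # (n,) int8, 1 = male, 0 = female
    n_loci_dropped: int = 0  # oversampled loci lost to fixation and discarded

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_males(self) -> int:
        return int(self.sex.sum())

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


def _wf_generation(haps: np.ndarray, genome: Genome, n_next: int, rng: np.random.Generator) -> np.ndarray:
    """One Wright-Fisher generation: random distinct parent pairs."""
    n = haps.shape[0]
    sires = rng.integers(0, n, size=n_next)
    dams = rng.integers(0, n, size=n_next)
    clash = sires == dams
    while np.any(clash):
        dams[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = sires == dams
    g1 = meiose_batch(haps[sires], genome, rng)
    g2 = meiose_batch(haps[dams], genome, rng)
    return np.stack([g1, g2], axis=1)


def _subset_segregating(
    over: Genome, spec: GenomeSpec, freq: np.ndarray, seed: int
) -> tuple[Genome, np.ndarray]:
    """Pick spec-sized panels of segregating loci nearest the ideal even grid."""
    keep: list[int] = []
    seg = (freq > 0.0) & (freq < 1.0)
    for c, (start, stop) in enumerate(over.chrom_slices):
        for want_qtl, n_want in ((False, spec.snps_per_chrom), (True, spec.qtls_per_chrom)):
            cls = np.flatnonzero((over.chrom == c) & (over.is_qtl == want_qtl) & seg)
            if cls.size < n_want:
                raise RuntimeError(
                    f"chromosome {c}: only {cls.size} segregating "
                    f"{'QTL' if want_qtl else 'SNP'} loci remain after drift "
                    f"({n_want} required); increase the oversampling multiplier"
                )
            if n_want == 1:
                target = np.array([spec.chrom_length / 2.0])
            else:
                target = np.linspace(0.0, spec.chrom_length, n_want)
            avail_pos = over.pos[cls]
            taken = np.zeros(cls.size, bool)
            for t in target:
                order = np.argsort(np.abs(avail_pos - t), kind="stable")
                for j in order:
                    if not taken[j]:
                        taken[j] = True
                        keep.append(int(cls[j]))
                        break
    keep_arr = np.array(sorted(keep), dtype=np.int64)
    effects = sample_qtl_effects(spec.n_qtls, spec.gamma_shape, spec.gamma_scale, stream(seed, "historical", "effects"))
    sub = Genome(
        spec=spec,
        chrom=over.chrom[keep_arr].copy(),
        pos=over.pos[keep_arr].copy(),
        is_qtl=over.is_qtl[keep_arr].copy(),
        qtl_effects=effects,
    )
    return sub, keep_arr


def run_historical(
    genome_or_spec: Genome | GenomeSpec,
    schedule: HistoricalSchedule,
    seed: int,
    oversample: float = 1.5,
) -> FounderSet:
    """Simulate the historical population and return the founder set.

    The genome is laid out with ``oversample`` times the requested loci per
    class, drifted through the schedule, expanded by random mating into
    ``expansion_size`` founders, and finally subset back to the requested
    locus counts using only loci still segregating among the founders.
    """
    spec = genome_or_spec.spec if isinstance(genome_or_spec, Genome) else genome_or_spec
    if oversample < 1.0:
        raise ValueError("oversample multiplier must be >= 1")
    over_spec = GenomeSpec(
        n_chromosomes=spec.n_chromosomes,
        chrom_length=spec.chrom_length,
        snps_per_chrom=int(np.ceil(spec.snps_per_chrom * oversample)),
        qtls_per_chrom=int(np.ceil(spec.qtls_per_chrom * oversample)),
        gamma_shape=spec.gamma_shape,
        gamma_scale=spec.gamma_scale,
    )
    rng = stream(seed, "historical")
    over = Genome(
        spec=over_spec,
        **_layout_only(over_spec),
        qtl_effects=np.zeros(over_spec.n_qtls),
    )

    sizes = schedule.sizes()
    n0 = int(sizes[0]) if sizes.size else schedule.expansion_size
    haps = rng.integers(0, 2, size=(n0, 2, over.n_loci), dtype=np.uint8)
    for n_next in sizes[1:]:
        haps = _wf_generation(haps, over, int(n_next), rng)

    haps = _wf_generation(haps, over, schedule.expansion_size, rng)
    sex = np.zeros(schedule.expansion_size, dtype=np.int8)
    sex[rng.choice(schedule.expansion_size, size=schedule.expansion_males, replace=False)] = 1

    freq = haps.mean(axis=(0, 1))
    final_genome, keep = _subset_segregating(over, spec, freq, seed)
    dropped = over.n_loci - keep.size
    return FounderSet(
        genome=final_genome,
        haplotypes=np.ascontiguousarray(haps[:, :, keep]),
        sex=sex,
        n_loci_dropped=dropped,
    )


def _layout_only(spec: GenomeSpec) -> dict:
    """Marker/QTL layout arrays for ``spec`` (no effect sampling)."""
    from .genome import _even_positions

    snp_pos = _even_positions(spec.snps_per_chrom, spec.chrom_length)
    qtl_pos = (np.arange(spec.qtls_per_chrom) + 0.5) * spec.chrom_length / spec.qtls_per_chrom
    if np.min(np.abs(snp_pos[:, None] - qtl_pos[None, :])) < 1e-12:
        half_snp = spec.chrom_length / max(spec.snps_per_chrom - 1, 1) / 2.0
        qtl_pos = np.clip(qtl_pos + half_snp, 0.0, spec.chrom_length - 1e-9)
    per_pos = np.concatenate([snp_pos, qtl_pos])
    per_qtl = np.concatenate([np.zeros(spec.snps_per_chrom, bool), np.ones(spec.qtls_per_chrom, bool)])
    order = np.argsort(per_pos, kind="stable")
    return {
        "chrom": np.repeat(np.arange(spec.n_chromosomes, dtype=np.int16), per_pos.size),
        "pos": np.tile(per_pos[order], spec.n_chromosomes),
        "is_qtl": np.tile(per_qtl[order], spec.n_chromosomes),
    }
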