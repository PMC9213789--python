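"""Gamete formation under the Haldane recombination model.

Crossover counts per chromosome are Poisson with mean equal to the genetic
length in Morgans, crossover positions are uniform (no interference), and
chromosomes assort independently. Implemented as a batch operation across
many meioses at once; the per-individual ``meiosis`` wrapper exists for
convenience and tests.
"""

from __future__ import annotations

import numpy as np

from .genome import Genome

__all__ = ["meiose_batch", "meiosis"]


def meiose_batch(haplotypes: np.ndarray, genome: Genome, rng: np.random.Generator) -> np.ndarray:
    """Produce one gamete per parent.

    Parameters
    ----------
    haplotypes
        uint8 array of shape ``(n, 2, n_loci)``; row ``i`` holds the two
        haplotypes of the parent of meiosis ``i`` (rows may repeat when one
        parent produces several gametes).
    genome
        Locus map giving chromosome boundaries and positions in Morgans.
    rng
        Source of randomness.

    Returns
    -------
    uint8 array of shape ``(n, n_loci)``.
    """
    haps = haplotypes
    if haps.ndim != 3 or haps.shape[1] != 2 or haps.shape[2] != genome.n_loci:
        raise ValueError("haplotypes must have shape (n, 2, n_loci)")
    n = haps.shape[0]
    gametes = np.empty((n, genome.n_loci), dtype=np.uint8)
    length = genome.spec.chrom_length

    for start, stop in genome.chrom_slices:
        m = stop - start
        pos = genome.pos[start:stop]
        # Which haplotype each locus is copied from: start phase plus the
        # parity of the number of crossovers at positions below the locus.
        phase0 = rng.integers(0, 2, size=n, dtype=np.int64)
        counts = rng.poisson(length, size=n)
        total = int(counts.sum())
        if total:
            xpos = rng.uniform(0.0, length, size=total)
            owner = np.repeat(np.arange(n), counts)
            bins = np.searchsorted(pos, xpos)
            flips = np.zeros((n, m + 1), dtype=np.int64)
            np.add.at(flips, (owner, bins), 1)
            parity = (phase0[:, None] + np.cumsum(flips, axis=1)[:, :m]) & 1
        else:
            parity = np.broadcast_to((phase0 & 1)[:, None], (n, m))
        block = haps[:, :, start:stop]
        gametes[:, start:stop] = np.where(parity == 0, block[:, 0, :], block[:, 1, :])
    return gametes


def meiosis(parent: np.ndarray, genome: Genome, seed: int | np.random.Generator) -> np.ndarray:
    """One gamete from a single parent's haplotype pair ``(2, n_loci)``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return meiose_batch(parent[None, :, :], genome, rng)[0]
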