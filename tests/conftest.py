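"""Shared fixtures: tiny populations that keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from nucleusgs import (
    GenomeSpec,
    HerdConfig,
    HistoricalSchedule,
    build_genome,
    calibrate_trait,
    run_historical,
    simulate_herd,
)


@pytest.fixture(scope="session")
def tiny_spec() -> GenomeSpec:
    return GenomeSpec(n_chromosomes=3, snps_per_chrom=60, qtls_per_chrom=6)


@pytest.fixture(scope="session")
def tiny_genome(tiny_spec):
    return build_genome(tiny_spec, seed=7)


@pytest.fixture(scope="session")
def tiny_founders(tiny_spec):
    schedule = HistoricalSchedule(
        phases=((25, 80, 80), (4, 80, 24)), expansion_size=120, expansion_males=20
    )
    return run_historical(tiny_spec, schedule, seed=7, oversample=2.0)


@pytest.fixture(scope="session")
def tiny_sim(tiny_founders):
    """A small selected herd: 4 boars x 40 sows x 5 generations."""
    trait = calibrate_trait(tiny_founders, 0.3)
    config = HerdConfig(n_boars=4, n_sows=40, sows_per_boar=10, n_generations=5)
    return simulate_herd(
        tiny_founders, trait, config, seed=13, phen_scheme=(1, 1), phenotype_generations=(1, 4)
    )


def random_pedigree(n: int, n_founders: int, seed: int, max_parent_gap: int = 200):
    """Random topologically ordered pedigree with sexes; oracle-test helper."""
    rng = np.random.default_rng(seed)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = rng.integers(0, 2, size=n)
    sex[0], sex[1] = 1, 0  # guarantee one of each among founders
    for i in range(n_founders, n):
        lo = max(0, i - max_parent_gap)
        prev = np.arange(lo, i)
        males = prev[sex[prev] == 1]
        females = prev[sex[prev] == 0]
        if males.size == 0 or females.size == 0:
            continue
        sire[i] = rng.choice(males)
        dam[i] = rng.choice(females)
    return sire, dam, sex
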