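"""Nucleus-herd simulator: census invariants, selection, phenotyping."""

import dataclasses

import numpy as np
import pytest

from nucleusgs import (
    HerdConfig,
    calibrate_trait,
    initialize_herd,
    produce_generation,
    record_phenotypes,
    select_replacements,
    simulate_herd,
)
from nucleusgs.herd import HerdState
from nucleusgs._seeding import stream


@pytest.fixture(scope="module")
def small_config():
    return HerdConfig(n_boars=4, n_sows=40, sows_per_boar=10, n_generations=3)


@pytest.fixture(scope="module")
def trait(tiny_founders):
    return calibrate_trait(tiny_founders, 0.3)


class TestHerdConfig:
    def test_census_consistency_enforced(self):
        with pytest.raises(ValueError, match="sows_per_boar"):
            HerdConfig(n_boars=30, n_sows=1000, sows_per_boar=40)

    def test_default_structure(self):
        cfg = HerdConfig()
        assert (cfg.n_boars, cfg.n_sows, cfg.litter_size) == (30, 1200, 10)

    @pytest.mark.parametrize("field,value", [("sow_replacement", 1.4), ("raising_rate", -0.1)])
    def test_proportions_bounded(self, field, value):
        with pytest.raises(ValueError):
            HerdConfig(**{field: value})


class TestInitialize:
    def test_herd_counts(self, tiny_founders, small_config, trait):
        pop, state = initialize_herd(tiny_founders, small_config, trait, seed=0)
        assert state.boars.size == 4
        assert state.sows.size == 40
        assert np.all(pop.sex[state.boars] == 1)
        assert np.all(pop.sex[state.sows] == 0)

    def test_insufficient_founders_rejected_with_shortfall(self, tiny_founders, trait):
        cfg = HerdConfig(n_boars=25, n_sows=250, sows_per_boar=10, n_generations=2)
        with pytest.raises(ValueError, match="25 boars"):
            initialize_herd(tiny_founders, cfg, trait, seed=0)


class TestProduceGeneration:
    def test_litter_counts_and_sex_ratio(self, tiny_founders, small_config, trait):
        pop, state = initialize_herd(tiny_founders, small_config, trait, seed=1)
        rng = stream(1, "test")
        off = produce_generation(pop, state, tiny_founders.genome, trait, small_config, 1, rng)
        assert off.size == 40 * 10
        for litter in pop.litters_of_generation(1):
            assert litter.size == 10
            assert (pop.sex[litter] == 1).sum() == 5

    def test_each_boar_gets_its_mating_group(self, tiny_founders, small_config, trait):
        pop, state = initialize_herd(tiny_founders, small_config, trait, seed=2)
        rng = stream(2, "test")
        produce_generation(pop, state, tiny_founders.genome, trait, small_config, 1, rng)
        off = pop.rows_of_generation(1)
        sires, counts = np.unique(pop.sire[off], return_counts=True)
        assert sires.size == 4
        assert np.all(counts == 10 * 10)  # 10 sows x 10 piglets per boar

    def test_offspring_alleles_drawn_from_parents(self, tiny_founders, small_config, trait):
        pop, state = initialize_herd(tiny_founders, small_config, trait, seed=3)
        rng = stream(3, "test")
        off = produce_generation(pop, state, tiny_founders.genome, trait, small_config, 1, rng)
        snp = tiny_founders.genome.snp_index
        dosage = pop.snp_dosage()
        for r in off[:25]:
            child = dosage[r].astype(int)
            s, d = pop.sire[r], pop.dam[r]
            lo = (
                np.clip(dosage[s].astype(int) - 1, 0, 1) + np.clip(dosage[d].astype(int) - 1, 0, 1)
            )
            hi = np.clip(dosage[s], 0, 1).astype(int) + np.clip(dosage[d], 0, 1).astype(int)
            assert np.all(child >= lo) and np.all(child <= hi)


class TestRecordPhenotypes:
    def test_scheme_counts(self, tiny_sim):
        pop = tiny_sim.population
        rec1 = pop.phen_recorded & (pop.generation == 1)
        assert rec1.sum() == 40 * 2  # one male + one female per litter

    def test_scheme_11_on_fresh_generation(self, tiny_founders, small_config, trait):
        pop, state = initialize_herd(tiny_founders, small_config, trait, seed=4)
        rng = stream(4, "test")
        produce_generation(pop, state, tiny_founders.genome, trait, small_config, 1, rng)
        table = record_phenotypes(pop, 1, (1, 2), rng)
        assert len(table) == 40 * 3
        assert (pop.sex[table["id"]] == 1).sum() == 40

    def test_empty_scheme_records_nothing(self, tiny_founders, small_config, trait):
        pop, state = initialize_herd(tiny_founders, small_config, trait, seed=5)
        rng = stream(5, "test")
        produce_generation(pop, state, tiny_founders.genome, trait, small_config, 1, rng)
        assert len(record_phenotypes(pop, 1, (0, 0), rng)) == 0

    def test_oversized_scheme_rejected(self, tiny_founders, small_config, trait):
        pop, state = initialize_herd(tiny_founders, small_config, trait, seed=6)
        rng = stream(6, "test")
        produce_generation(pop, state, tiny_founders.genome, trait, small_config, 1, rng)
        with pytest.raises(ValueError):
            record_phenotypes(pop, 1, (6, 0), rng)


class TestSelection:
    def test_truncation_property_and_replacement_counts(self, tiny_founders, small_config, trait):
        pop, state = initialize_herd(tiny_founders, small_config, trait, seed=7)
        rng = stream(7, "test")
        produce_generation(pop, state, tiny_founders.genome, trait, small_config, 1, rng)
        crit = stream(7, "crit").random(pop.n)
        new = select_replacements(pop, state, crit, small_config, 1, rng)
        assert new.boars.size == 4 and new.sows.size == 40
        # boars fully replaced from generation-1 raised males
        assert np.all(pop.generation[new.boars] == 1)
        # 40% sow replacement: 16 new, 24 kept
        assert (pop.generation[new.sows] == 1).sum() == 16
        # truncation: worst selected male >= best unselected raised male
        off = pop.rows_of_generation(1)
        pool = off[(pop.sex[off] == 1) & pop.raised[off]]
        unsel = np.setdiff1d(pool, new.boars)
        assert crit[new.boars].min() >= crit[unsel].max()

    def test_selection_reproducible(self, tiny_founders, small_config, trait):
        picks = []
        for _ in range(2):
            pop, state = initialize_herd(tiny_founders, small_config, trait, seed=8)
            rng = stream(8, "test")
            produce_generation(pop, state, tiny_founders.genome, trait, small_config, 1, rng)
            crit = stream(8, "crit").random(pop.n)
            picks.append(select_replacements(pop, state, crit, small_config, 1, rng).boars)
        assert np.array_equal(picks[0], picks[1])

    def test_pool_too_small_rejected(self, tiny_founders, small_config, trait):
        pop, state = initialize_herd(tiny_founders, small_config, trait, seed=9)
        rng = stream(9, "test")
        crit = np.zeros(pop.n)
        with pytest.raises(ValueError):  # no offspring produced yet
            select_replacements(pop, state, crit, small_config, 1, rng)


class TestSimulateHerd:
    def test_census_invariants_every_generation(self, tiny_sim):
        pop = tiny_sim.population
        for g in range(1, 6):
            off = pop.rows_of_generation(g)
            assert off.size == 400
            assert (pop.sex[off] == 1).sum() == 200

    def test_pedigree_is_generation_ordered(self, tiny_sim):
        pop = tiny_sim.population
        has_parent = pop.sire >= 0
        assert np.all(
            pop.generation[pop.sire[has_parent]] < pop.generation[has_parent]
        )
        assert np.all(pop.sire[has_parent] < np.flatnonzero(has_parent))

    def test_selection_raises_mean_tbv_while_random_does_not(self, tiny_founders):
        trait = calibrate_trait(tiny_founders, 0.4)
        cfg_sel = HerdConfig(n_boars=4, n_sows=40, sows_per_boar=10, n_generations=5)
        cfg_rnd = dataclasses.replace(cfg_sel, selection_criterion="random")
        gains_sel, gains_rnd = [], []
        for rep in range(3):
            s = simulate_herd(tiny_founders, trait, cfg_sel, seed=20 + rep)
            r = simulate_herd(tiny_founders, trait, cfg_rnd, seed=20 + rep)
            gains_sel.append(s.summaries.mean_tbv.iloc[-1] - s.summaries.mean_tbv.iloc[0])
            gains_rnd.append(r.summaries.mean_tbv.iloc[-1] - r.summaries.mean_tbv.iloc[0])
        assert np.mean(gains_sel) > np.mean(gains_rnd) + 0.2
        assert abs(np.mean(gains_rnd)) < 0.3

    def test_genetic_variance_declines_under_selection(self, tiny_sim):
        v = tiny_sim.summaries.var_tbv.to_numpy()
        assert v[-1] < v[0]
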