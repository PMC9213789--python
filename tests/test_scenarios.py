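"""Scenario layer: designs, schemes, leakage guards, determinism."""

import numpy as np
import pytest

from nucleusgs import (
    GenotypingScheme,
    ReferenceDesign,
    ScenarioConfig,
    build_candidates,
    build_reference,
    desk_scaled_config,
    evaluate_design,
    run_scenario,
    simulate_study,
    summarize_sweep,
)
from nucleusgs.genome import GenomeSpec
from nucleusgs.herd import HerdConfig
from nucleusgs.historical import HistoricalSchedule


def micro_config(study="reference", h2=0.3, n_generations=None):
    """A deliberately tiny end-to-end configuration for fast tests."""
    return ScenarioConfig(
        genome=GenomeSpec(n_chromosomes=3, snps_per_chrom=60, qtls_per_chrom=6),
        schedule=HistoricalSchedule(
            phases=((25, 80, 80), (4, 80, 24)), expansion_size=120, expansion_males=20
        ),
        herd=HerdConfig(
            n_boars=4,
            n_sows=40,
            sows_per_boar=10,
            n_generations=n_generations or (8 if study == "reference" else 5),
        ),
        h2=h2,
        study=study,
        oversample=2.0,
        reml_repeats=1,
    )


@pytest.fixture(scope="module")
def ref_sim():
    cfg = micro_config("reference")
    return cfg, simulate_study(cfg, seed=31)


@pytest.fixture(scope="module")
def cand_sim():
    cfg = micro_config("candidate")
    return cfg, simulate_study(cfg, seed=32)


class TestDesignValidation:
    def test_case1_proportions(self):
        ReferenceDesign(case="same_generation_proportion", proportion=60)
        with pytest.raises(ValueError):
            ReferenceDesign(case="same_generation_proportion", proportion=25)

    def test_unknown_case(self):
        with pytest.raises(ValueError):
            ReferenceDesign(case="bogus")

    def test_scheme_legal_splits(self):
        GenotypingScheme(ratio=30, males=2, females=1)
        with pytest.raises(ValueError):
            GenotypingScheme(ratio=20, males=2, females=1)
        with pytest.raises(ValueError):
            GenotypingScheme(ratio=40, males=2, females=2)

    def test_fifty_percent_1to1_alternates(self):
        s = GenotypingScheme(ratio=50, males=1, females=1)
        assert s.alternating and (s.males, s.females) == (3, 2)
        assert s.label == "50%-1:1"


class TestBuildSets:
    def test_case1_counts(self, ref_sim):
        cfg, sim = ref_sim
        ref = build_reference(sim, ReferenceDesign(case="same_generation_proportion", proportion=20), seed=1)
        n_litters = cfg.herd.n_sows
        assert ref.size == 2 * n_litters
        last = cfg.herd.n_generations - 1
        assert np.all(sim.population.generation[ref] == last)

    def test_single_generation_counts(self, ref_sim):
        cfg, sim = ref_sim
        ref = build_reference(sim, ReferenceDesign(case="single_generation", generation=3), seed=2)
        assert ref.size == 2 * cfg.herd.n_sows
        assert np.all(sim.population.generation[ref] == 3)

    def test_cumulative_window_counts(self, ref_sim):
        cfg, sim = ref_sim
        ref = build_reference(sim, ReferenceDesign(case="cumulative_generations", window=(4, 7)), seed=3)
        assert ref.size == 4 * 2 * cfg.herd.n_sows

    def test_window_beyond_last_reference_generation_rejected(self, ref_sim):
        cfg, sim = ref_sim
        with pytest.raises(ValueError):
            build_reference(sim, ReferenceDesign(case="cumulative_generations", window=(4, 20)), seed=4)

    def test_candidates_never_phenotyped_and_disjoint(self, ref_sim):
        cfg, sim = ref_sim
        ref = build_reference(sim, ReferenceDesign(case="same_generation_proportion", proportion=40), seed=5)
        cand = build_candidates(sim, (1, 1), seed=5)
        assert np.intersect1d(ref, cand).size == 0
        assert not sim.population.phen_recorded[cand].any()

    def test_scheme_sex_composition(self, cand_sim):
        cfg, sim = cand_sim
        cand = build_candidates(sim, GenotypingScheme(ratio=30, males=2, females=1), seed=6)
        assert cand.size == 3 * cfg.herd.n_sows
        assert (sim.population.sex[cand] == 1).sum() == 2 * cfg.herd.n_sows

    def test_all_female_scheme(self, cand_sim):
        cfg, sim = cand_sim
        cand = build_candidates(sim, GenotypingScheme(ratio=50, males=0, females=5), seed=7)
        assert np.all(sim.population.sex[cand] == 0)

    def test_alternating_scheme_balances_sexes(self, cand_sim):
        cfg, sim = cand_sim
        cand = build_candidates(sim, GenotypingScheme(ratio=50, males=1, females=1), seed=8)
        males = (sim.population.sex[cand] == 1).sum()
        assert cand.size == 5 * cfg.herd.n_sows
        assert males == pytest.approx(cand.size / 2, abs=3)


class TestEvaluate:
    def test_reference_evaluation_outputs(self, ref_sim):
        cfg, sim = ref_sim
        res = evaluate_design(
            sim, cfg, seed=41, design=ReferenceDesign(case="same_generation_proportion", proportion=40)
        )
        assert -1 <= res["acc_overall"] <= 1
        assert res["sigma_a2"] > 0 and res["sigma_e2"] > 0
        assert res["n_candidates"] == 2 * cfg.herd.n_sows

    def test_evaluation_is_deterministic_and_side_effect_free(self, ref_sim):
        cfg, sim = ref_sim
        design = ReferenceDesign(case="single_generation", generation=5)
        before = sim.population.genotyped.copy()
        r1 = evaluate_design(sim, cfg, seed=42, design=design)
        r2 = evaluate_design(sim, cfg, seed=42, design=design)
        assert r1 == r2
        assert np.array_equal(sim.population.genotyped, before)

    def test_candidate_evaluation_includes_gain_and_baseline(self, cand_sim):
        cfg, sim = cand_sim
        res = evaluate_design(sim, cfg, seed=43, scheme=GenotypingScheme(ratio=20, males=1, females=1))
        for key in ("gain", "gain_blup", "gain_vs_blup_pct", "acc_path_male", "acc_path_female"):
            assert key in res
        assert res["gain"] > 0
        # intensities come from the configured selected fractions
        assert res["i_male"] > res["i_female"] > 0

    def test_candidate_phenotypes_stay_hidden(self, cand_sim):
        """Leakage guard: a candidate row never contributes a record."""
        cfg, sim = cand_sim
        pop = sim.population
        cand = build_candidates(sim, GenotypingScheme(ratio=20, males=1, females=1), seed=44)
        phen = np.flatnonzero(pop.phen_recorded)
        assert np.intersect1d(phen, cand).size == 0


class TestRunScenarioAndSweep:
    def test_same_seed_same_result(self):
        cfg = micro_config("reference", n_generations=6)
        cfg = ScenarioConfig(**{**cfg.__dict__, "design": ReferenceDesign(case="single_generation", generation=4)})
        a = run_scenario(cfg, n_replicates=1, root_seed=9)
        b = run_scenario(cfg, n_replicates=1, root_seed=9)
        assert a.replicates.equals(b.replicates)

    def test_sweep_requires_three_points(self):
        with pytest.raises(ValueError):
            summarize_sweep([(1, 0.2), (2, 0.3)])
        with pytest.raises(ValueError, match="constant"):
            summarize_sweep([(1, 0.2), (1, 0.3), (1, 0.4)])

    def test_sweep_correlation_and_monotone_flags(self):
        out = summarize_sweep([(480, 0.2), (960, 0.3), (1440, 0.42), (1920, 0.5)])
        assert out["r"] > 0.99
        assert out["monotone_increasing"]
        assert not out["monotone_decreasing"]

    def test_desk_preset_structure(self):
        cfg = desk_scaled_config("reference")
        assert cfg.herd.sows_per_boar == 40  # full design's mating ratio
        assert cfg.herd.n_sows == cfg.herd.n_boars * 40
        assert cfg.genome.n_snps == 14 * 300
        cfg_c = desk_scaled_config("candidate")
        assert cfg_c.herd.n_generations == 5
        assert cfg_c.herd.sows_per_boar == 40
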