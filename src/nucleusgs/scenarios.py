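"""Experiment designs: reference-population construction and candidate genotyping.

Two studies are expressed declaratively:

* the **reference study** — a 20-generation herd in which the reference
  population (animals with both genotypes and phenotypes) is built four
  ways: per-litter proportions of generation 19 (case 1), a single earlier
  generation (case 2), a window of cumulated generations ending at 19
  (case 3), and same-total-size comparisons between cases 1 and 3 (case 4);
  candidates are one male and one female per generation-20 litter,
  genotyped but never phenotyped;
* the **candidate study** — a 5-generation herd phenotyped one male and two
  females per litter (generations 1-4), with one male and one female per
  litter as the genomic reference; generation-5 litters are genotyped under
  ratio x sex-split schemes (20/30/50% of the litter) and scored by GEBV
  accuracy per sex and by expected genetic gain over the sire/dam pathways,
  against a pedigree-BLUP baseline fitted to the same populations.

Replicates re-run the whole pipeline (historical population onward) under
named child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._seeding import stream
from .genome import GenomeSpec
from .herd import HerdConfig, SimulatedHerd, simulate_herd
from .historical import HistoricalSchedule, run_historical
from .metrics import accuracy, selection_intensity, sex_pathway_gain
from .mme import solve_mme
from .pedigree import a_inverse, a_submatrix
from .relationship import genomic_relationship, h_inverse
from .reml import VarianceComponents, reml_varcomp
from .trait import calibrate_trait

__all__ = [
    "ReferenceDesign",
    "GenotypingScheme",
    "ScenarioConfig",
    "ScenarioResult",
    "desk_scaled_config",
    "paper_full_config",
    "simulate_study",
    "build_reference",
    "build_candidates",
    "evaluate_design",
    "run_scenario",
    "summarize_sweep",
]

_CASES = ("same_generation_proportion", "single_generation", "cumulative_generations")
_LEGAL_SPLITS = {
    20: {(2, 0), (1, 1), (0, 2)},
    30: {(3, 0), (2, 1), (1, 1), (1, 2), (0, 3)},
    50: {(5, 0), (4, 1), (3, 2), (1, 1), (2, 3), (1, 4), (0, 5)},
}


@dataclass(frozen=True)
class ReferenceDesign:
    """One way of building the reference population (reference study)."""

    case: str
    proportion: int | None = None  # percent of each generation-19 litter (case 1)
    generation: int | None = None  # single source generation (case 2)
    window: tuple[int, int] | None = None  # inclusive generation span (case 3)

    def __post_init__(self) -> None:
        if self.case not in _CASES:
            raise ValueError(f"unknown reference design case {self.case!r}")
        if self.case == "same_generation_proportion":
            if self.proportion not in (20, 40, 60, 80, 100):
                raise ValueError("proportion must be one of 20/40/60/80/100 percent")
        elif self.case == "single_generation":
            if self.generation is None or self.generation < 1:
                raise ValueError("single_generation design needs a source generation >= 1")
        else:
            if self.window is None or self.window[0] > self.window[1] or self.window[0] < 1:
                raise ValueError("cumulative design needs a window (first, last) with first <= last")


@dataclass(frozen=True)
class GenotypingScheme:
    """Candidate-study genotyping: per-litter male/female counts.

    ``ratio`` is the percent of each 10-piglet litter genotyped. The 50%
    1:1 split cannot be realised inside a 5-animal draw, so it alternates
    3:2 and 2:3 litters (``alternating`` is set automatically), keeping the
    population-level sex ratio at 1:1.
    """

    ratio: int
    males: int
    females: int
    alternating: bool = False

    def __post_init__(self) -> None:
        if self.ratio not in _LEGAL_SPLITS:
            raise ValueError("genotyping ratio must be 20, 30 or 50 percent")
        if (self.males, self.females) not in _LEGAL_SPLITS[self.ratio]:
            raise ValueError(
                f"split {self.males}:{self.females} is not a legal {self.ratio}% scheme"
            )
        if self.ratio == 50 and (self.males, self.females) == (1, 1):
            object.__setattr__(self, "males", 3)
            object.__setattr__(self, "females", 2)
            object.__setattr__(self, "alternating", True)

    @property
    def label(self) -> str:
        if self.alternating:
            return f"{self.ratio}%-1:1"
        return f"{self.ratio}%-{self.males}:{self.females}"


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one scenario end to end."""

    genome: GenomeSpec
    schedule: HistoricalSchedule
    herd: HerdConfig
    h2: float = 0.3
    study: str = "reference"  # reference | candidate
    design: ReferenceDesign | None = None
    scheme: GenotypingScheme | None = None
    n_replicates: int = 10
    blend: float = 0.05
    reml_repeats: int = 3
    reml_subset_frac: float = 0.9
    reml_max_n: int = 3000
    oversample: float = 1.5
    # Selected fractions for the gain pathways: boars and sows retained per
    # year out of the raised offspring of each sex (38 and 200 of 4800 at
    # the full census).
    selected_frac_male: float = 38.0 / 4800.0
    selected_frac_female: float = 200.0 / 4800.0

    def __post_init__(self) -> None:
        if self.study not in ("reference", "candidate"):
            raise ValueError("study must be 'reference' or 'candidate'")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie strictly between 0 and 1")


@dataclass
class ScenarioResult:
    """Replicate-level rows plus a mean/SD summary."""

    config: ScenarioConfig
    replicates: pd.DataFrame
    root_seed: int

    @property
    def summary(self) -> pd.DataFrame:
        num = self.replicates.select_dtypes("number").drop(columns=["replicate", "seed"], errors="ignore")
        return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def desk_scaled_config(study: str = "reference", h2: float = 0.3, **overrides) -> ScenarioConfig:
    """Desk-scale preset: herd and genome scaled to run in minutes.

    Both presets keep the full design's 1:40 boar:sow mating ratio — the
    40-litter half-sib sire families are what ties reference and candidate
    populations together, and shrinking them costs far more accuracy than
    shrinking the census. The 20-generation reference study runs at 12
    boars x 480 sows (two fifths of the sow herd; 12 sires keep
    inbreeding tolerable over 20 generations), the 5-generation candidate
    study at 6 boars x 240 sows (one fifth; 6-sire drift is immaterial
    over four selection rounds). The genome carries 14 chromosomes x 300
    SNPs with the historical bottleneck drift-scaled so the effective
    number of genome segments shrinks roughly with the census.

    The reference preset estimates variance components on a 1,200-record
    subsample (candidate accuracy is insensitive to the shrinkage ratio);
    the candidate preset keeps full-record REML because sigma_A feeds the
    reported gains.
    """
    genome = GenomeSpec(n_chromosomes=14, snps_per_chrom=300, qtls_per_chrom=17)
    if study == "reference":
        # bottleneck Ne scales with the 2/5 sow herd so N_ref/Me matches the
        # full design (drift-scaled: same cumulative t/N through the neck)
        schedule = HistoricalSchedule(
            phases=((200, 600, 600), (8, 600, 160)), expansion_size=820, expansion_males=30
        )
        herd = HerdConfig(n_boars=12, n_sows=480, sows_per_boar=40, n_generations=20)
        reml_max_n = 1200
    else:
        schedule = HistoricalSchedule(
            phases=((200, 600, 600), (4, 600, 80)), expansion_size=410, expansion_males=30
        )
        herd = HerdConfig(n_boars=6, n_sows=240, sows_per_boar=40, n_generations=5)
        reml_max_n = 3000
    cfg = ScenarioConfig(
        genome=genome, schedule=schedule, herd=herd, h2=h2, study=study, reml_max_n=reml_max_n
    )
    return replace(cfg, **overrides) if overrides else cfg


def paper_full_config(study: str = "reference", h2: float = 0.3, **overrides) -> ScenarioConfig:
    """Full-census preset (30 boars x 1200 sows, 18 x 2834 SNPs); hours of runtime."""
    genome = GenomeSpec()
    schedule = HistoricalSchedule()
    herd = HerdConfig(n_generations=20 if study == "reference" else 5)
    cfg = ScenarioConfig(genome=genome, schedule=schedule, herd=herd, h2=h2, study=study)
    return replace(cfg, **overrides) if overrides else cfg


def simulate_study(config: ScenarioConfig, seed: int) -> SimulatedHerd:
    """Historical population -> trait calibration -> recent herd, one replicate.

    The reference study records one male and one female phenotype per litter
    every generation but the last; the candidate study records one male and
    two females for generations 1..4.
    """
    founders = run_historical(
        config.genome, config.schedule, seed=seed, oversample=config.oversample
    )
    trait = calibrate_trait(founders, config.h2)
    scheme = (1, 1) if config.study == "reference" else (1, 2)
    last_phen = config.herd.n_generations - 1
    return simulate_herd(
        founders,
        trait,
        config.herd,
        seed=seed,
        phen_scheme=scheme,
        phenotype_generations=(1, last_phen),
    )


def _per_litter_sample(
    pop,
    g: int,
    n_males: int,
    n_females: int,
    rng: np.random.Generator,
    prefer_recorded: bool = False,
    alternating: bool = False,
) -> np.ndarray:
    """Random per-litter draw of the requested sex counts from generation g."""
    out = []
    for k, litter in enumerate(pop.litters_of_generation(g)):
        nm, nf = n_males, n_females
        if alternating and k % 2 == 1:
            nm, nf = nf, nm
        for sex_val, want in ((1, nm), (0, nf)):
            cand = litter[pop.sex[litter] == sex_val]
            if want > cand.size:
                raise ValueError(
                    f"litter {k} of generation {g} has {cand.size} animals of sex "
                    f"{sex_val}, fewer than the {want} requested"
                )
            if want == 0:
                continue
            if prefer_recorded:
                rec = cand[pop.phen_recorded[cand]]
                oth = cand[~pop.phen_recorded[cand]]
                take = rec[rng.permutation(rec.size)][:want]
                if take.size < want:
                    extra = oth[rng.choice(oth.size, size=want - take.size, replace=False)]
                    take = np.concatenate([take, extra])
            else:
                take = cand[rng.choice(cand.size, size=want, replace=False)]
            out.append(take)
    return np.sort(np.concatenate(out))


def build_reference(sim: SimulatedHerd, design: ReferenceDesign, seed: int | np.random.Generator) -> np.ndarray:
    """Rows of the reference population; marked genotyped (and phenotyped).

    Per-litter draws favour animals whose phenotypes were already recorded
    during the simulation, so the 1M+1F designs coincide with the records
    that drove selection, and larger designs reveal additional phenotypes.
    """
    pop = sim.population
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "reference")
    last = sim.config.n_generations - 1  # reference generations end here
    if design.case == "same_generation_proportion":
        per_sex = design.proportion // 20
        rows = _per_litter_sample(pop, last, per_sex, per_sex, rng, prefer_recorded=True)
    elif design.case == "single_generation":
        if not 1 <= design.generation <= last:
            raise ValueError(f"source generation must lie in 1..{last}")
        rows = _per_litter_sample(pop, design.generation, 1, 1, rng, prefer_recorded=True)
    else:
        first, lastw = design.window
        if lastw > last:
            raise ValueError(f"window may not extend past generation {last}")
        rows = np.concatenate(
            [
                _per_litter_sample(pop, g, 1, 1, rng, prefer_recorded=True)
                for g in range(first, lastw + 1)
            ]
        )
    pop.genotyped[rows] = True
    return rows


def build_candidates(
    sim: SimulatedHerd,
    scheme: GenotypingScheme | tuple[int, int],
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Rows of the genotyped candidate set in the final generation.

    Candidates are genotyped and never phenotyped; a plain ``(n_m, n_f)``
    tuple stands for the reference-study default of one male and one female
    per last-generation litter.
    """
    pop = sim.population
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "candidates")
    g = sim.config.n_generations
    if isinstance(scheme, GenotypingScheme):
        rows = _per_litter_sample(
            pop, g, scheme.males, scheme.females, rng, alternating=scheme.alternating
        )
    else:
        rows = _per_litter_sample(pop, g, scheme[0], scheme[1], rng)
    pop.genotyped[rows] = True
    return rows


def _cached_ainv(sim: SimulatedHerd):
    cache = sim.__dict__.setdefault("_eval_cache", {})
    if "ainv" not in cache:
        pop = sim.population
        cache["ainv"] = a_inverse(pop.sire, pop.dam)
    return cache["ainv"]


def _reml_on_rows(pop, rows: np.ndarray, config: ScenarioConfig, rng: np.random.Generator):
    if rows.size > config.reml_max_n:
        rows = np.sort(rng.choice(rows, size=config.reml_max_n, replace=False))
    K = a_submatrix(pop.sire, pop.dam, rows)
    return reml_varcomp(pop.phenotype[rows], np.ones((rows.size, 1)), K, n_repeats=1)


def _cached_reml(
    sim: SimulatedHerd,
    config: ScenarioConfig,
    seed: int,
    draw: "callable",
    cache_key: str,
):
    """Variance components for one design, averaged over re-drawn subsets.

    ``draw(rng)`` must return one random per-litter phenotyping subset of the
    design; the estimation is repeated on ``reml_repeats`` independent draws
    and averaged — the estimation protocol the study designs prescribe. The
    result is cached per design on the simulated population.
    """
    cache = sim.__dict__.setdefault("_eval_cache", {})
    key = ("reml", cache_key)
    if key not in cache:
        pop = sim.population
        rng = stream(seed, "reml", cache_key)
        fits = []
        seen = set()
        for _ in range(max(config.reml_repeats, 1)):
            rows = draw(rng)
            h = hash(rows.tobytes())
            if h in seen and fits:  # identical draw (e.g. whole litters): reuse
                fits.append(fits[-1])
                continue
            seen.add(h)
            fits.append(_reml_on_rows(pop, rows, config, rng))
        cache[key] = VarianceComponents(
            sigma_a2=float(np.mean([f.sigma_a2 for f in fits])),
            sigma_e2=float(np.mean([f.sigma_e2 for f in fits])),
            se_a2=float(np.mean([f.se_a2 for f in fits])),
            se_e2=float(np.mean([f.se_e2 for f in fits])),
            converged=all(f.converged for f in fits),
            iterations=int(np.max([f.iterations for f in fits])),
            boundary=any(f.boundary for f in fits),
        )
    return cache[key]


def _fit_and_score(
    sim: SimulatedHerd,
    phen_rows: np.ndarray,
    candidate_rows: np.ndarray,
    genotyped_rows: np.ndarray | None,
    config: ScenarioConfig,
    vc,
):
    """(ss)GBLUP or BLUP fit at the given variance ratio; returns EBV vector."""
    pop = sim.population
    phen_rows = np.setdiff1d(phen_rows, candidate_rows)  # leakage guard
    y = pop.phenotype[phen_rows]
    X = np.ones((phen_rows.size, 1))

    ainv = _cached_ainv(sim)
    if genotyped_rows is None or genotyped_rows.size == 0:
        kinv = ainv
    else:
        geno = np.unique(genotyped_rows)
        G = genomic_relationship(pop.snp_dosage(geno))
        a22 = a_submatrix(pop.sire, pop.dam, geno)
        kinv = h_inverse(ainv, a22, G, geno, blend=config.blend)
    sol = solve_mme(y, X, phen_rows, kinv, vc.lambda_mme)
    return sol.g


def _sex_accuracy(pop, rows: np.ndarray, ebv: np.ndarray, sex_val: int) -> float:
    sub = rows[pop.sex[rows] == sex_val]
    return accuracy(pop.tbv[sub], ebv[sub])


def evaluate_design(
    sim: SimulatedHerd,
    config: ScenarioConfig,
    seed: int,
    design: ReferenceDesign | None = None,
    scheme: GenotypingScheme | None = None,
    with_blup_baseline: bool | None = None,
) -> dict:
    """Evaluate one design or genotyping scheme on a simulated population.

    Returns a flat dict of accuracies, variance components, sizes and (for
    the candidate study) sire/dam-pathway genetic gains, for ssGBLUP and —
    when requested — the pedigree-BLUP baseline on the same population.
    """
    pop = sim.population
    rng = stream(seed, "evaluate")
    design = design if design is not None else config.design
    scheme = scheme if scheme is not None else config.scheme

    # Designs mark animals genotyped/phenotyped; keep those marks local to
    # this evaluation so designs sharing one simulated population stay
    # independent.
    saved_recorded = pop.phen_recorded.copy()
    saved_genotyped = pop.genotyped.copy()
    try:
        return _evaluate_inner(sim, config, seed, design, scheme, with_blup_baseline, rng)
    finally:
        pop.phen_recorded = saved_recorded
        pop.genotyped = saved_genotyped


def _design_draw(sim, design: ReferenceDesign):
    """Per-litter phenotype-subset sampler matching a reference design."""
    pop = sim.population
    last = sim.config.n_generations - 1

    def draw(rng: np.random.Generator) -> np.ndarray:
        if design.case == "same_generation_proportion":
            k = design.proportion // 20
            return _per_litter_sample(pop, last, k, k, rng)
        if design.case == "single_generation":
            return _per_litter_sample(pop, design.generation, 1, 1, rng)
        first, lastw = design.window
        return np.concatenate(
            [_per_litter_sample(pop, g, 1, 1, rng) for g in range(first, lastw + 1)]
        )

    return draw


def _evaluate_inner(sim, config, seed, design, scheme, with_blup_baseline, rng):
    pop = sim.population
    if config.study == "reference":
        if design is None:
            raise ValueError("reference study needs a ReferenceDesign")
        reference = build_reference(sim, design, rng)
        candidates = build_candidates(sim, (1, 1), rng)
        # Per-group protocol: the fit trains on the reference population's
        # phenotypes, so the design contrasts (reference size, generation
        # gap) are what the accuracy responds to.
        phen_rows = reference
        vc = _cached_reml(sim, config, seed, _design_draw(sim, design), repr(design))
    else:
        if scheme is None:
            raise ValueError("candidate study needs a GenotypingScheme")
        reference = build_reference(
            sim,
            ReferenceDesign(case="cumulative_generations", window=(1, sim.config.n_generations - 1)),
            rng,
        )
        candidates = build_candidates(sim, scheme, rng)
        phen_rows = np.flatnonzero(pop.phen_recorded)  # 1M+2F per litter, gens 1..last-1

        def draw_recorded(rng_: np.random.Generator) -> np.ndarray:
            return np.concatenate(
                [
                    _per_litter_sample(pop, g, 1, 2, rng_)
                    for g in range(1, sim.config.n_generations)
                ]
            )

        vc = _cached_reml(sim, config, seed, draw_recorded, "candidate_recorded")

    assert np.intersect1d(reference, candidates).size == 0
    genotyped = np.concatenate([reference, candidates])
    ebv = _fit_and_score(sim, phen_rows, candidates, genotyped, config, vc)

    out = {
        "n_reference": int(reference.size),
        "n_candidates": int(candidates.size),
        "sigma_a2": vc.sigma_a2,
        "sigma_e2": vc.sigma_e2,
        "sigma_p2": vc.sigma_p2,
        "reml_converged": bool(vc.converged),
        "acc_overall": accuracy(pop.tbv[candidates], ebv[candidates]),
        "acc_male": _sex_accuracy(pop, candidates, ebv, 1),
        "acc_female": _sex_accuracy(pop, candidates, ebv, 0),
    }

    if config.study == "candidate":
        g_last = sim.config.n_generations
        sigma_a = float(np.sqrt(max(vc.sigma_a2, 0.0)))
        i_m = selection_intensity(config.selected_frac_male)
        i_f = selection_intensity(config.selected_frac_female)

        def pathway_rows(sex_val: int, cand_rows: np.ndarray) -> np.ndarray:
            sub = cand_rows[pop.sex[cand_rows] == sex_val]
            if sub.size >= 2:
                return sub
            gen = pop.rows_of_generation(g_last)
            return gen[(pop.sex[gen] == sex_val) & pop.raised[gen]]

        r_m = accuracy(pop.tbv[pathway_rows(1, candidates)], ebv[pathway_rows(1, candidates)])
        r_f = accuracy(pop.tbv[pathway_rows(0, candidates)], ebv[pathway_rows(0, candidates)])
        out.update(
            {
                "acc_path_male": r_m,
                "acc_path_female": r_f,
                "gain": sex_pathway_gain(sigma_a, i_m, r_m, i_f, r_f),
                "sigma_a": sigma_a,
                "i_male": i_m,
                "i_female": i_f,
            }
        )
        if with_blup_baseline is None:
            with_blup_baseline = True
        if with_blup_baseline:
            # Same population, same records, same variance components — the
            # baseline differs only in dropping the genomic information.
            ebv_b = _fit_and_score(sim, phen_rows, candidates, None, config, vc)
            gen = pop.rows_of_generation(g_last)
            males = gen[(pop.sex[gen] == 1) & pop.raised[gen]]
            females = gen[(pop.sex[gen] == 0) & pop.raised[gen]]
            rb_m = accuracy(pop.tbv[males], ebv_b[males])
            rb_f = accuracy(pop.tbv[females], ebv_b[females])
            sigma_a_b = float(np.sqrt(max(vc.sigma_a2, 0.0)))
            out.update(
                {
                    "acc_male_blup": rb_m,
                    "acc_female_blup": rb_f,
                    "gain_blup": sex_pathway_gain(sigma_a_b, i_m, rb_m, i_f, rb_f),
                    "gain_vs_blup_pct": 100.0
                    * (out["gain"] - sex_pathway_gain(sigma_a_b, i_m, rb_m, i_f, rb_f))
                    / sex_pathway_gain(sigma_a_b, i_m, rb_m, i_f, rb_f),
                }
            )
    return out


def run_scenario(config: ScenarioConfig, n_replicates: int | None = None, root_seed: int = 0) -> ScenarioResult:
    """Run the configured scenario over independent replicate seeds."""
    n_rep = config.n_replicates if n_replicates is None else n_replicates
    rows = []
    for rep in range(n_rep):
        rep_seed = int(stream(root_seed, "scenario", rep).integers(0, 2**31 - 1))
        sim = simulate_study(config, rep_seed)
        res = evaluate_design(sim, config, rep_seed)
        res.update({"replicate": rep, "seed": rep_seed})
        rows.append(res)
    return ScenarioResult(config=config, replicates=pd.DataFrame(rows), root_seed=root_seed)


def summarize_sweep(results: list[tuple[float, float]] | pd.DataFrame, covariate: str = "covariate") -> dict:
    """Correlate mean accuracy with a design covariate across scenarios.

    Accepts ``(covariate, accuracy)`` pairs (or a DataFrame with those two
    columns) and returns the Pearson correlation, a monotone-trend flag and
    the fitted slope sign. At least three scenarios are required.
    """
    if isinstance(results, pd.DataFrame):
        arr = results.iloc[:, :2].to_numpy(dtype=float)
    else:
        arr = np.asarray(results, dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least three scenarios to summarise a sweep")
    x, yv = arr[:, 0], arr[:, 1]
    if np.std(x) == 0 or np.std(yv) == 0:
        raise ValueError("sweep correlation undefined: constant covariate or accuracy")
    r = float(np.corrcoef(x, yv)[0, 1])
    order = np.argsort(x)
    diffs = np.diff(yv[order])
    return {
        "covariate": covariate,
        "r": r,
        "monotone_increasing": bool(np.all(diffs >= 0)),
        "monotone_decreasing": bool(np.all(diffs <= 0)),
        "n": int(arr.shape[0]),
    }
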