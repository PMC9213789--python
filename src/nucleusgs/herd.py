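"""Recent (nucleus-herd) population: breeding, selection, phenotyping.

A closed herd of boars and sows is founded from the historical founder set
and advanced through discrete generations: sows are assigned to boars in
fixed-size mating groups, every sow produces one litter of fixed size and
sex ratio, and replacements are chosen by truncation on estimated breeding
values (pedigree BLUP on the phenotypes recorded so far), with the
configured boar/sow replacement rates. A configurable fraction of each
litter is raised and enters the selection pool.

Phenotypes are generated at birth for every individual (``P = TBV + e`` on
unit phenotypic variance) but only become visible to evaluations when
*recorded*; recording schemes pick a fixed number of males and females per
litter. Analyses may additionally reveal phenotypes of designated reference
animals, which mirrors how the study designs phenotype their reference
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import stream
from .genome import Genome
from .historical import FounderSet
from .meiosis import meiose_batch
from .mme import solve_mme
from .pedigree import a_inverse, inbreeding
from .trait import TraitModel, true_breeding_value

__all__ = [
    "HerdConfig",
    "Population",
    "SimulatedHerd",
    "initialize_herd",
    "produce_generation",
    "select_replacements",
    "record_phenotypes",
    "simulate_herd",
]


@dataclass(frozen=True)
class HerdConfig:
    """Census structure and update strategy of the closed nucleus herd."""

    n_boars: int = 30
    n_sows: int = 1200
    sows_per_boar: int = 40
    litter_size: int = 10
    males_per_litter: int = 5
    boar_replacement: float = 1.0
    sow_replacement: float = 0.4
    raising_rate: float = 0.8
    n_generations: int = 20
    selection_criterion: str = "EBV_pedigree"  # EBV_pedigree | random

    def __post_init__(self) -> None:
        if self.n_sows != self.n_boars * self.sows_per_boar:
            raise ValueError("n_sows must equal n_boars * sows_per_boar")
        if not 0 < self.males_per_litter <= self.litter_size:
            raise ValueError("males_per_litter must lie in (0, litter_size]")
        for name in ("boar_replacement", "sow_replacement", "raising_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.selection_criterion not in ("EBV_pedigree", "random"):
            raise ValueError("selection_criterion must be 'EBV_pedigree' or 'random'")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")


class Population:
    """Columnar pedigree population with per-animal state.

    Animals are rows; ``sire``/``dam`` are row indices (-1 unknown). The
    latent phenotype exists for everyone; ``phen_recorded`` marks which
    records are visible to evaluations by default.
    """

    def __init__(self, n_snps: int, store_genotypes: bool = True):
        self.sire = np.empty(0, np.int64)
        self.dam = np.empty(0, np.int64)
        self.sex = np.empty(0, np.int8)  # 1 male, 0 female
        self.generation = np.empty(0, np.int16)
        self.litter = np.empty(0, np.int64)  # -1 for founders
        self.tbv = np.empty(0, np.float64)
        self.phenotype = np.empty(0, np.float64)
        self.phen_recorded = np.empty(0, bool)
        self.genotyped = np.empty(0, bool)
        self.raised = np.empty(0, bool)
        self.ebv = np.empty(0, np.float64)
        self.store_genotypes = store_genotypes
        self._dosage_blocks: list[np.ndarray] = []
        self.n_snps = n_snps

    @property
    def n(self) -> int:
        return self.sire.size

    def append(self, **cols) -> np.ndarray:
        """Append a block of animals; returns their row indices."""
        k = cols["sire"].size
        start = self.n
        dosage = cols.pop("snp_dosage", None)
        for name, arr in cols.items():
            setattr(self, name, np.concatenate([getattr(self, name), arr]))
        if self.store_genotypes:
            if dosage is None or dosage.shape != (k, self.n_snps):
                raise ValueError("snp_dosage block of shape (k, n_snps) required")
            self._dosage_blocks.append(np.ascontiguousarray(dosage, dtype=np.uint8))
        return np.arange(start, start + k)

    def snp_dosage(self, rows: np.ndarray | None = None) -> np.ndarray:
        if not self.store_genotypes:
            raise ValueError("genotypes were not stored for this population")
        if len(self._dosage_blocks) > 1:
            self._dosage_blocks = [np.concatenate(self._dosage_blocks, axis=0)]
        full = self._dosage_blocks[0] if self._dosage_blocks else np.empty((0, self.n_snps), np.uint8)
        return full if rows is None else full[np.asarray(rows)]

    def rows_of_generation(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.generation == g)

    def litters_of_generation(self, g: int) -> list[np.ndarray]:
        rows = self.rows_of_generation(g)
        if rows.size == 0:
            return []
        order = rows[np.argsort(self.litter[rows], kind="stable")]
        return [order[s] for s in np.split(np.arange(order.size), np.flatnonzero(np.diff(self.litter[order])) + 1)]

    def inbreeding(self) -> np.ndarray:
        return inbreeding(self.sire, self.dam)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "sire": self.sire,
                "dam": self.dam,
                "sex": self.sex,
                "generation": self.generation,
                "litter": self.litter,
                "tbv": self.tbv,
                "phenotype": self.phenotype,
                "phen_recorded": self.phen_recorded,
                "genotyped": self.genotyped,
                "raised": self.raised,
                "ebv": self.ebv,
            }
        )


@dataclass
class HerdState:
    """Current breeding animals and their haplotypes."""

    boars: np.ndarray  # population rows
    sows: np.ndarray
    haplotypes: dict = field(default_factory=dict)  # row -> (2, L) uint8

    def hap_matrix(self, rows: np.ndarray) -> np.ndarray:
        return np.stack([self.haplotypes[int(r)] for r in rows])


def _phenotypes_for(tbv: np.ndarray, trait: TraitModel, rng: np.random.Generator) -> np.ndarray:
    return tbv + rng.normal(0.0, trait.residual_sd, size=tbv.size)


def initialize_herd(
    founders: FounderSet,
    config: HerdConfig,
    trait: TraitModel,
    seed: int | np.random.Generator,
    store_genotypes: bool = True,
) -> tuple[Population, HerdState]:
    """Found the herd: boars and sows drawn at random from the founder set."""
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "herd_init")
    males = np.flatnonzero(founders.sex == 1)
    females = np.flatnonzero(founders.sex == 0)
    if males.size < config.n_boars or females.size < config.n_sows:
        raise ValueError(
            f"founders provide {males.size} males / {females.size} females but the herd "
            f"needs {config.n_boars} boars / {config.n_sows} sows"
        )
    boars_f = rng.choice(males, size=config.n_boars, replace=False)
    sows_f = rng.choice(females, size=config.n_sows, replace=False)
    chosen = np.concatenate([boars_f, sows_f])
    genome = founders.genome
    haps = founders.haplotypes[chosen]
    tbv = true_breeding_value(haps, genome, trait)

    pop = Population(n_snps=genome.snp_index.size, store_genotypes=store_genotypes)
    k = chosen.size
    rows = pop.append(
        sire=np.full(k, -1, np.int64),
        dam=np.full(k, -1, np.int64),
        sex=np.concatenate([np.ones(config.n_boars, np.int8), np.zeros(config.n_sows, np.int8)]),
        generation=np.zeros(k, np.int16),
        litter=np.full(k, -1, np.int64),
        tbv=tbv,
        phenotype=_phenotypes_for(tbv, trait, rng),
        phen_recorded=np.zeros(k, bool),
        genotyped=np.zeros(k, bool),
        raised=np.ones(k, bool),
        ebv=np.full(k, np.nan),
        snp_dosage=genome.snp_dosage(haps) if store_genotypes else None,
    )
    state = HerdState(boars=rows[: config.n_boars], sows=rows[config.n_boars :])
    state.haplotypes = {int(r): haps[i] for i, r in enumerate(rows)}
    return pop, state


def produce_generation(
    pop: Population,
    state: HerdState,
    genome: Genome,
    trait: TraitModel,
    config: HerdConfig,
    g: int,
    rng: np.random.Generator,
    litter_offset: int = 0,
) -> np.ndarray:
    """Mate the herd into one litter per sow; returns offspring rows.

    Sows are shuffled into mating groups of ``sows_per_boar`` per boar;
    each litter carries ``litter_size`` offspring with exactly
    ``males_per_litter`` males. Offspring get haplotypes by meiosis, a TBV,
    a latent phenotype and a raised flag (random ``raising_rate`` of each
    litter).
    """
    n_litters = state.sows.size
    ls, mpl = config.litter_size, config.males_per_litter
    sow_order = rng.permutation(state.sows)
    litter_sire = np.repeat(np.repeat(state.boars, config.sows_per_boar)[:n_litters], ls)
    litter_dam = np.repeat(sow_order, ls)

    n_off = n_litters * ls
    sire_haps = state.hap_matrix(litter_sire)
    dam_haps = state.hap_matrix(litter_dam)
    gam_s = meiose_batch(sire_haps, genome, rng)
    gam_d = meiose_batch(dam_haps, genome, rng)
    haps = np.stack([gam_s, gam_d], axis=1)

    sex = np.zeros((n_litters, ls), np.int8)
    sex[:, :mpl] = 1
    sex = sex.reshape(-1)
    litter_id = litter_offset + np.repeat(np.arange(n_litters), ls)

    raised = np.zeros((n_litters, ls), bool)
    n_raised = int(round(config.raising_rate * ls))
    for i in range(n_litters):
        raised[i, rng.choice(ls, size=n_raised, replace=False)] = True

    tbv = true_breeding_value(haps, genome, trait)
    rows = pop.append(
        sire=litter_sire,
        dam=litter_dam,
        sex=sex,
        generation=np.full(n_off, g, np.int16),
        litter=litter_id,
        tbv=tbv,
        phenotype=_phenotypes_for(tbv, trait, rng),
        phen_recorded=np.zeros(n_off, bool),
        genotyped=np.zeros(n_off, bool),
        raised=raised.reshape(-1),
        ebv=np.full(n_off, np.nan),
        snp_dosage=genome.snp_dosage(haps) if pop.store_genotypes else None,
    )
    for i, r in enumerate(rows):
        state.haplotypes[int(r)] = haps[i]
    return rows


def record_phenotypes(
    pop: Population, g: int, scheme: tuple[int, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Record ``(n_males, n_females)`` random phenotypes per litter of generation g."""
    n_m, n_f = scheme
    out_rows = []
    for litter in pop.litters_of_generation(g):
        for sex_val, want in ((1, n_m), (0, n_f)):
            cand = litter[pop.sex[litter] == sex_val]
            if want > cand.size:
                raise ValueError(
                    f"scheme requests {want} phenotypes of sex {sex_val} but the litter has {cand.size}"
                )
            if want:
                out_rows.append(rng.choice(cand, size=want, replace=False))
    rows = np.sort(np.concatenate(out_rows)) if out_rows else np.empty(0, np.int64)
    pop.phen_recorded[rows] = True
    return pd.DataFrame({"id": rows, "phenotype": pop.phenotype[rows]})


def _pedigree_ebv(pop: Population, lam: float) -> np.ndarray:
    """Pedigree-BLUP EBVs from the currently recorded phenotypes."""
    rec = np.flatnonzero(pop.phen_recorded)
    if rec.size == 0:
        return np.zeros(pop.n)
    ainv = a_inverse(pop.sire, pop.dam)
    y = pop.phenotype[rec]
    X = np.ones((rec.size, 1))
    sol = solve_mme(y, X, rec, ainv, lam)
    return sol.g


def select_replacements(
    pop: Population,
    state: HerdState,
    criterion_values: np.ndarray,
    config: HerdConfig,
    g: int,
    rng: np.random.Generator,
) -> HerdState:
    """Truncation selection of the next herd with the configured replacement rates.

    All replacement boars/sows come from the raised fraction of generation
    ``g``'s offspring; retained incumbents are the top-ranked current
    breeders. Ties are broken by a seeded random draw.
    """

    def top(rows: np.ndarray, k: int) -> np.ndarray:
        if k > rows.size:
            raise ValueError(f"need {k} animals but only {rows.size} are available")
        if k == 0:
            return rows[:0]
        jitter = rng.random(rows.size)
        order = np.lexsort((jitter, -criterion_values[rows]))
        return rows[order[:k]]

    off = pop.rows_of_generation(g)
    pool_m = off[(pop.sex[off] == 1) & pop.raised[off]]
    pool_f = off[(pop.sex[off] == 0) & pop.raised[off]]

    n_new_b = int(round(config.boar_replacement * config.n_boars))
    n_new_s = int(round(config.sow_replacement * config.n_sows))
    new_boars = top(pool_m, n_new_b)
    kept_boars = top(state.boars, config.n_boars - n_new_b)
    new_sows = top(pool_f, n_new_s)
    kept_sows = top(state.sows, config.n_sows - n_new_s)

    boars = np.concatenate([kept_boars, new_boars])
    sows = np.concatenate([kept_sows, new_sows])
    haps = {int(r): state.haplotypes[int(r)] for r in np.concatenate([boars, sows])}
    return HerdState(boars=boars, sows=sows, haplotypes=haps)


@dataclass
class SimulatedHerd:
    """A fully simulated herd plus its genome, trait and summaries."""

    population: Population
    genome: Genome
    trait: TraitModel
    config: HerdConfig
    seed: int
    summaries: pd.DataFrame
    n_litters_per_gen: int


def simulate_herd(
    founders: FounderSet,
    trait: TraitModel,
    config: HerdConfig,
    seed: int,
    phen_scheme: tuple[int, int] = (1, 1),
    phenotype_generations: tuple[int, int] | None = None,
    store_genotypes: bool = True,
) -> SimulatedHerd:
    """Advance the herd ``n_generations``; returns the full population.

    ``phen_scheme`` phenotypes are recorded per litter for generations in
    ``phenotype_generations`` (default: every generation except the last,
    whose offspring are the selection candidates of the study designs).
    Selection uses pedigree-BLUP EBVs on the recorded phenotypes (or a
    random criterion), with the base-trait variance ratio as shrinkage.
    """
    genome = founders.genome
    rng = stream(seed, "herd")
    pop, state = initialize_herd(founders, config, trait, rng, store_genotypes=store_genotypes)
    first, last = (1, config.n_generations - 1) if phenotype_generations is None else phenotype_generations
    lam = trait.lambda_mme

    rows_summary = []
    for g in range(1, config.n_generations + 1):
        off = produce_generation(pop, state, genome, trait, config, g, rng, litter_offset=(g - 1) * config.n_sows)
        if first <= g <= last:
            record_phenotypes(pop, g, phen_scheme, rng)
        if g < config.n_generations:
            if config.selection_criterion == "EBV_pedigree":
                crit = _pedigree_ebv(pop, lam)
                pop.ebv[:] = crit
            else:
                crit = rng.random(pop.n)
            state = select_replacements(pop, state, crit, config, g, rng)
            keep = set(int(r) for r in np.concatenate([state.boars, state.sows]))
            state.haplotypes = {r: h for r, h in state.haplotypes.items() if r in keep}
        rows_summary.append(
            {
                "generation": g,
                "mean_tbv": float(pop.tbv[off].mean()),
                "var_tbv": float(pop.tbv[off].var()),
                "n_offspring": int(off.size),
            }
        )
    return SimulatedHerd(
        population=pop,
        genome=genome,
        trait=trait,
        config=config,
        seed=seed,
        summaries=pd.DataFrame(rows_summary),
        n_litters_per_gen=config.n_sows,
    )
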