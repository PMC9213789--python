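"""File formats: pedigree CSV, PLINK ped/map genotypes, scenario configs.

Pedigree files use columns ``id,sire,dam,sex,generation`` with ``0`` for an
unknown parent and 1-based ids in file space (internally animals are 0-based
row indices). Genotypes are exchanged as plain-text PLINK ``.ped``/``.map``
pairs with A/B allele coding. Scenario configurations are YAML with a
versioned schema; unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import Genome, GenomeSpec
from .herd import HerdConfig
from .historical import HistoricalSchedule
from .scenarios import GenotypingScheme, ReferenceDesign, ScenarioConfig

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "export_plink",
    "import_plink",
    "load_config",
    "save_config",
]

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "generation"]
CONFIG_SCHEMA_VERSION = 1


def write_pedigree(path: str | Path, table: pd.DataFrame) -> None:
    """Write a pedigree CSV (columns id,sire,dam,sex,generation; 0 = unknown)."""
    df = table[PEDIGREE_COLUMNS].copy()
    df.to_csv(path, index=False)


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read and validate a pedigree CSV.

    Rejects (naming the offending line): missing columns, duplicate ids,
    self-parenting, parents that do not precede their offspring, and
    sex-inconsistent parents (a sire that appears as a dam, etc.).
    """
    df = pd.read_csv(path)
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pedigree columns {missing}")
    df = df[PEDIGREE_COLUMNS].astype(np.int64)
    ids = df["id"].to_numpy()
    if np.unique(ids).size != ids.size:
        dup = df[df.duplicated("id")].index[0] + 2
        raise ValueError(f"{path}: duplicate animal id at line {dup}")
    pos = {int(i): k for k, i in enumerate(ids)}
    for line, (i, s, d, sex) in enumerate(
        zip(ids, df["sire"], df["dam"], df["sex"]), start=2
    ):
        for parent, want_sex in ((int(s), 1), (int(d), 0)):
            if parent == 0:
                continue
            if parent == int(i):
                raise ValueError(f"{path}: line {line}: animal {i} is its own parent")
            if parent not in pos or pos[parent] >= pos[int(i)]:
                raise ValueError(
                    f"{path}: line {line}: parent {parent} does not precede animal {i}"
                )
            psex = int(df["sex"].iloc[pos[parent]])
            if psex != want_sex:
                which = "sire" if want_sex == 1 else "dam"
                raise ValueError(
                    f"{path}: line {line}: {which} {parent} has sex {psex}"
                )
    return df


def pedigree_frame(pop) -> pd.DataFrame:
    """File-space pedigree (1-based ids, 0 = unknown) for a Population."""
    return pd.DataFrame(
        {
            "id": np.arange(pop.n) + 1,
            "sire": np.where(pop.sire < 0, 0, pop.sire + 1),
            "dam": np.where(pop.dam < 0, 0, pop.dam + 1),
            "sex": pop.sex.astype(np.int64),
            "generation": pop.generation.astype(np.int64),
        }
    )


def export_plink(
    pop,
    rows: np.ndarray,
    genome: Genome,
    prefix: str | Path,
) -> tuple[Path, Path]:
    """Write PLINK ``.ped``/``.map`` for the given (genotyped) animals.

    The ``.map`` carries chromosome, marker name, genetic position in cM and
    a physical-position surrogate (cM x 1e4, integral). Dosage d is coded as
    the allele pair ``A A`` (0), ``A B`` (1), ``B B`` (2).
    """
    rows = np.asarray(rows, dtype=np.int64)
    if not np.all(pop.genotyped[rows]):
        bad = rows[~pop.genotyped[rows]][0]
        raise ValueError(f"animal {bad} is not genotyped; cannot export")
    prefix = Path(prefix)
    snp = genome.snp_index
    chrom = genome.chrom[snp] + 1
    cm = genome.pos[snp] * 100.0
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, (c, p) in enumerate(zip(chrom, cm)):
            fh.write(f"{c}\tsnp{c}_{j}\t{p:.6f}\t{int(round(p * 1e4)) + 1}\n")

    dosage = pop.snp_dosage(rows)
    allele_pairs = np.array(["A A", "A B", "B B"])
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for r, drow in zip(rows, dosage):
            sire = pop.sire[r] + 1 if pop.sire[r] >= 0 else 0
            dam = pop.dam[r] + 1 if pop.dam[r] >= 0 else 0
            sex_code = 1 if pop.sex[r] == 1 else 2
            lead = f"1 {r + 1} {sire} {dam} {sex_code} -9"
            fh.write(lead + " " + " ".join(allele_pairs[drow]) + "\n")
    return prefix.with_suffix(".ped"), prefix.with_suffix(".map")


def import_plink(prefix: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Read a ``.ped``/``.map`` pair back into (ids, dosage matrix, map frame)."""
    prefix = Path(prefix)
    map_df = pd.read_csv(
        prefix.with_suffix(".map"),
        sep="\t",
        names=["chrom", "marker", "cm", "bp"],
    )
    ids, rows = [], []
    code = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2}
    with open(prefix.with_suffix(".ped")) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if (len(parts) - 6) != 2 * len(map_df):
                raise ValueError(
                    f"{prefix}.ped: line {line_no}: expected {2 * len(map_df)} allele "
                    f"columns, found {len(parts) - 6}"
                )
            ids.append(int(parts[1]))
            alleles = parts[6:]
            rows.append([code[(alleles[2 * j], alleles[2 * j + 1])] for j in range(len(map_df))])
    return np.array(ids), np.array(rows, dtype=np.uint8), map_df


def _asdict_clean(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: v for k, v in d.items() if not k.startswith("_")}


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    doc = {
        "schema_version": CONFIG_SCHEMA_VERSION,
        "genome": _asdict_clean(config.genome),
        "historical": {
            "phases": [list(p) for p in config.schedule.phases],
            "expansion_size": config.schedule.expansion_size,
            "expansion_males": config.schedule.expansion_males,
        },
        "herd": _asdict_clean(config.herd),
        "trait": {"h2": config.h2},
        "study": config.study,
        "replicates": config.n_replicates,
        "evaluation": {
            "blend": config.blend,
            "reml_repeats": config.reml_repeats,
            "reml_subset_frac": config.reml_subset_frac,
            "reml_max_n": config.reml_max_n,
            "oversample": config.oversample,
            "selected_frac_male": config.selected_frac_male,
            "selected_frac_female": config.selected_frac_female,
        },
    }
    if config.design is not None:
        d = _asdict_clean(config.design)
        doc["reference"] = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items() if v is not None}
    if config.scheme is not None:
        doc["genotyping"] = {
            "ratio": config.scheme.ratio,
            "males": config.scheme.males,
            "females": config.scheme.females,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _take(section: dict, allowed: set[str], where: str) -> dict:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")
    return section


def load_config(path: str | Path) -> ScenarioConfig:
    """Parse a YAML scenario config; unknown keys anywhere are an error."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    top_allowed = {
        "schema_version", "genome", "historical", "herd", "trait", "study",
        "replicates", "evaluation", "reference", "genotyping", "seed",
    }
    _take(doc, top_allowed, "top level")
    if doc.get("schema_version", CONFIG_SCHEMA_VERSION) != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {doc['schema_version']}")

    gspec = GenomeSpec(**_take(doc.get("genome", {}), {f.name for f in dataclasses.fields(GenomeSpec)}, "genome"))
    hist = doc.get("historical", {})
    _take(hist, {"phases", "expansion_size", "expansion_males"}, "historical")
    schedule = HistoricalSchedule(
        phases=tuple(tuple(p) for p in hist.get("phases", HistoricalSchedule().phases)),
        expansion_size=hist.get("expansion_size", 2050),
        expansion_males=hist.get("expansion_males", 50),
    )
    herd = HerdConfig(**_take(doc.get("herd", {}), {f.name for f in dataclasses.fields(HerdConfig)}, "herd"))
    trait = _take(doc.get("trait", {}), {"h2"}, "trait")
    ev = _take(
        doc.get("evaluation", {}),
        {"blend", "reml_repeats", "reml_subset_frac", "reml_max_n", "oversample",
         "selected_frac_male", "selected_frac_female"},
        "evaluation",
    )
    design = None
    if "reference" in doc:
        ref = _take(doc["reference"], {"case", "proportion", "generation", "window"}, "reference")
        if "window" in ref and ref["window"] is not None:
            ref = {**ref, "window": tuple(ref["window"])}
        design = ReferenceDesign(**ref)
    scheme = None
    if "genotyping" in doc:
        gt = _take(doc["genotyping"], {"ratio", "males", "females"}, "genotyping")
        scheme = GenotypingScheme(**gt)
    return ScenarioConfig(
        genome=gspec,
        schedule=schedule,
        herd=herd,
        h2=trait.get("h2", 0.3),
        study=doc.get("study", "reference"),
        design=design,
        scheme=scheme,
        n_replicates=doc.get("replicates", 10),
        **ev,
    )
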