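"""Additive trait model: true breeding values and heritability calibration.

The trait is purely additive: an individual's true breeding value (TBV) is
the dosage-weighted sum of signed QTL effects, centered so the founder
generation has mean zero. Raw gamma-distributed effects are rescaled once so
that the founder TBV variance equals the target heritability on a unit
phenotypic variance, and the residual standard deviation is set to
``sqrt(1 - h2)``; phenotypes are then ``P = TBV + e`` with unit variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Genome
from .historical import FounderSet

__all__ = ["TraitModel", "true_breeding_value", "raw_breeding_values", "calibrate_trait"]


@dataclass(frozen=True)
class TraitModel:
    """Heritability, QTL-effect scaling and residual spread of one trait."""

    h2: float
    effect_scale: float  # multiplier applied to the genome's raw QTL effects
    residual_sd: float  # trait units
    tbv_center: float  # raw-scale founder mean TBV; scaled TBV = scale*(raw - center)

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("heritability must lie strictly between 0 and 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    @property
    def lambda_mme(self) -> float:
        """Mixed-model shrinkage ratio sigma_e^2 / sigma_a^2 at the base values."""
        return (self.residual_sd**2) / self.h2

    def tbv(self, raw: np.ndarray) -> np.ndarray:
        return self.effect_scale * (np.asarray(raw, dtype=float) - self.tbv_center)


def raw_breeding_values(qtl_dosage: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Uncentered, unscaled TBV: dosage (n, n_qtl) times signed effects."""
    return np.asarray(qtl_dosage, dtype=float) @ np.asarray(effects, dtype=float)


def true_breeding_value(
    haplotypes: np.ndarray, genome: Genome, trait: TraitModel | None = None
) -> np.ndarray:
    """TBV for haplotypes of shape (n, 2, L) (or a single (2, L) pair).

    With no ``trait``, returns the raw uncentered values; with a calibrated
    trait, applies the founder-mean centering and effect scaling.
    """
    single = haplotypes.ndim == 2
    haps = haplotypes[None] if single else haplotypes
    raw = raw_breeding_values(genome.qtl_dosage(haps), genome.qtl_effects)
    out = raw if trait is None else trait.tbv(raw)
    return float(out[0]) if single else out


def calibrate_trait(founders: FounderSet, target_h2: float) -> TraitModel:
    """Scale QTL effects so founder TBV variance equals ``target_h2``.

    Phenotypic variance is fixed at 1, so ``residual_sd = sqrt(1 - h2)`` and
    the founder generation realises the requested narrow-sense heritability
    exactly. Calibration is idempotent and invariant to a common rescaling
    of the raw effects.
    """
    if not 0.0 < target_h2 < 1.0:
        raise ValueError("target_h2 must lie strictly between 0 and 1")
    raw = raw_breeding_values(founders.genome.qtl_dosage(founders.haplotypes), founders.genome.qtl_effects)
    v = float(np.var(raw))
    if v <= 0:
        raise ValueError(
            "founders carry zero genetic variance (all QTL fixed or effects zero); cannot calibrate"
        )
    scale = float(np.sqrt(target_h2 / v))
    return TraitModel(
        h2=target_h2,
        effect_scale=scale,
        residual_sd=float(np.sqrt(1.0 - target_h2)),
        tbv_center=float(np.mean(raw)),
    )
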