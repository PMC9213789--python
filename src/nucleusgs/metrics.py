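"""Selection metrics: prediction accuracy, intensity and genetic gain."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["accuracy", "selection_intensity", "genetic_gain", "sex_pathway_gain"]


def accuracy(tbv: np.ndarray, ebv: np.ndarray) -> float:
    """Pearson correlation between true and estimated breeding values."""
    tbv = np.asarray(tbv, dtype=np.float64)
    ebv = np.asarray(ebv, dtype=np.float64)
    if tbv.size != ebv.size or tbv.size < 2:
        raise ValueError("tbv and ebv must have equal length >= 2")
    if np.std(tbv) == 0 or np.std(ebv) == 0:
        raise ValueError("accuracy is undefined when either vector has zero variance")
    return float(np.corrcoef(tbv, ebv)[0, 1])


def selection_intensity(p: float) -> float:
    """Standardised selection differential of truncating the top fraction ``p``.

    For a standard normal trait, ``i = phi(z) / p`` with ``z`` the upper-p
    quantile; ``p = 1`` (no selection) gives 0.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("selected proportion must lie in (0, 1]")
    if p == 1.0:
        return 0.0
    z = stats.norm.isf(p)
    return float(stats.norm.pdf(z) / p)


def genetic_gain(sigma_a: float, i: float, r_ai: float, L: float = 1.0) -> float:
    """Expected gain per generation: ``dG = sigma_A * i * r_AI / L``."""
    if sigma_a < 0:
        raise ValueError("sigma_a must be non-negative")
    if L <= 0:
        raise ValueError("generation interval must be positive")
    return sigma_a * i * r_ai / L


def sex_pathway_gain(
    sigma_a: float,
    i_male: float,
    r_male: float,
    i_female: float,
    r_female: float,
    L: float = 1.0,
) -> float:
    """Gain averaged over the sire and dam selection pathways.

    ``dG = sigma_A * (i_m * r_m + i_f * r_f) / 2 / L`` — each parent
    contributes half the genes of the next generation.
    """
    if sigma_a < 0:
        raise ValueError("sigma_a must be non-negative")
    if L <= 0:
        raise ValueError("generation interval must be positive")
    return sigma_a * 0.5 * (i_male * r_male + i_female * r_female) / L
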