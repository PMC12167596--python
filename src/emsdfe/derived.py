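"""Downstream evolutionary quantities computed from fitted DFE parameters.

Conventions follow the source analysis: the per-generation mutational
variance is V_m = rate * sigma^2 with the spontaneous diploid genomic rate
of fitness-affecting mutations (0.16 per generation) — sigma^2 only, with
no dosage factor — and mutational heritability is h2_m = V_m / V_e with
V_e = eta^2 (residual noise variance alone).  Generation-count
extrapolations are closed-form arithmetic, with rounding conventions
passed explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPONTANEOUS_RATE_PER_GENERATION",
    "mutational_variance",
    "mutational_heritability",
    "genetic_variance_across_founders",
    "generations_to_target_h2",
    "generations_to_overlap",
    "vg_to_vm_ratio",
    "ems_spectrum_fraction",
    "DerivedReport",
    "derived_report",
]

#: diploid genomic rate of spontaneous mutations affecting biomass/fitness
SPONTANEOUS_RATE_PER_GENERATION = 0.16


def mutational_variance(
    sigma: float, rate_per_generation: float = SPONTANEOUS_RATE_PER_GENERATION
) -> float:
    """Per-generation variance input from new mutations, V_m = rate * sigma^2."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if rate_per_generation <= 0:
        raise ValueError("rate must be positive")
    return rate_per_generation * sigma ** 2


def mutational_heritability(
    sigma: float, eta: float,
    rate_per_generation: float = SPONTANEOUS_RATE_PER_GENERATION,
) -> float:
    """Mutational heritability h2_m = rate * sigma^2 / eta^2 (per generation)."""
    if eta <= 0:
        raise ValueError("eta must be positive")
    return mutational_variance(sigma, rate_per_generation) / eta ** 2


def genetic_variance_across_founders(values) -> float:
    """Sample variance (n-1 denominator) of founder genetic values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two genetic values")
    return float(np.var(values, ddof=1))


def generations_to_target_h2(
    target_h2: float, h2m: float, rounding: str | None = "nearest_hundred"
) -> float:
    """Generations of mutation accumulation to reach heritability ``target_h2``.

    ``rounding`` is one of None (exact ratio), ``"nearest_hundred"`` or
    ``"ceil"`` — always explicit, never silent.
    """
    if h2m <= 0:
        raise ValueError("h2m must be positive")
    if not 0 < target_h2 < 1:
        raise ValueError("target_h2 must be in (0, 1)")
    x = target_h2 / h2m
    if rounding is None:
        return x
    if rounding == "nearest_hundred":
        return float(round(x / 100.0) * 100)
    if rounding == "ceil":
        return float(math.ceil(x))
    raise ValueError(f"unknown rounding convention {rounding!r}")


def generations_to_overlap(y_high: float, y_low: float, v_m_low: float) -> float:
    """Generations for the low founder's mutational fitness distribution to
    contain the high founder's mean within 2 SDs: (y_high - y_low)^2 / (4 V_m)."""
    if v_m_low <= 0:
        raise ValueError("v_m_low must be positive")
    return (y_high - y_low) ** 2 / (4.0 * v_m_low)


def vg_to_vm_ratio(v_g: float, v_m: float) -> float:
    """How many generations' worth of mutational variance the standing
    across-founder genetic variance represents."""
    if v_m <= 0:
        raise ValueError("v_m must be positive")
    return v_g / v_m


def ems_spectrum_fraction(snm_rate: float = 7e-9, indel_rate: float = 1.3e-9) -> float:
    """Percent of the spontaneous mutation spectrum covered by an EMS-style
    mutagen that induces point mutations but no indels."""
    if snm_rate <= 0 or indel_rate < 0:
        raise ValueError("rates must be positive (indel rate may be zero)")
    return 100.0 * snm_rate / (snm_rate + indel_rate)


@dataclass(frozen=True)
class DerivedReport:
    """All derived quantities for a pair of focal founders plus references."""

    v_m: dict[str, float]
    h2_m: dict[str, float]
    mean_h2_m: float
    v_g: float
    generations_to_target: float
    generations_to_overlap: float
    vg_to_vm: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "v_m": self.v_m,
            "h2_m": self.h2_m,
            "mean_h2_m": self.mean_h2_m,
            "v_g": self.v_g,
            "generations_to_target_h2": self.generations_to_target,
            "generations_to_overlap": self.generations_to_overlap,
            "vg_to_vm_ratio": self.vg_to_vm,
        }


def derived_report(
    genetic_values: dict[str, float],
    sigma: dict[str, float],
    eta: dict[str, float],
    high_founder: str,
    low_founder: str,
    rate_per_generation: float = SPONTANEOUS_RATE_PER_GENERATION,
    target_h2: float = 0.5,
) -> DerivedReport:
    """Assemble every derived quantity from point estimates.

    ``genetic_values`` covers all founders (for V_g); ``sigma`` and ``eta``
    cover the focal founders.  The overlap extrapolation uses the low
    founder's mutational variance.
    """
    v_m = {f: mutational_variance(s, rate_per_generation) for f, s in sigma.items()}
    h2 = {
        f: mutational_heritability(sigma[f], eta[f], rate_per_generation)
        for f in sigma
    }
    mean_h2 = float(np.mean(list(h2.values())))
    v_g = genetic_variance_across_founders(list(genetic_values.values()))
    return DerivedReport(
        v_m=v_m,
        h2_m=h2,
        mean_h2_m=mean_h2,
        v_g=v_g,
        generations_to_target=generations_to_target_h2(target_h2, mean_h2),
        generations_to_overlap=generations_to_overlap(
            genetic_values[high_founder], genetic_values[low_founder],
            v_m[low_founder],
        ),
        vg_to_vm={f: vg_to_vm_ratio(v_g, vm) for f, vm in v_m.items()},
    )
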