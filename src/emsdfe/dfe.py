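"""Distributions of single-mutation fitness effects (DFE families).

The inference itself is nonparametric — only the first two moments (mu,
sigma) of the DFE are ever estimated — but the simulator and the central
limit theorem diagnostics need concrete families to draw effects from.
Every family exposes its exact mean and SD in closed form (log10 mg scale)
so the compound-Poisson moment formulas can be checked against simulation
for arbitrarily shaped, including strongly skewed, effect distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = [
    "DFESpec",
    "PointMassDFE",
    "NormalDFE",
    "GammaDeleteriousDFE",
    "ReflectedGammaDFE",
    "TwoComponentMixtureDFE",
    "dfe_from_dict",
]


@dataclass(frozen=True)
class DFESpec:
    """Base class: a distribution of per-mutation effects on log10 biomass."""

    family: str = "base"

    def mean_sd(self) -> tuple[float, float]:
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raise NotImplementedError

    def to_dict(self) -> dict[str, Any]:
        d = {k: v for k, v in self.__dict__.items()}
        return d


@dataclass(frozen=True)
class PointMassDFE(DFESpec):
    """Every mutation has the same effect ``effect``."""

    effect: float = 0.0
    family: str = "point_mass"

    def mean_sd(self) -> tuple[float, float]:
        return float(self.effect), 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, float(self.effect))


@dataclass(frozen=True)
class NormalDFE(DFESpec):
    mean: float = 0.0
    sd: float = 0.01
    family: str = "normal"

    def mean_sd(self) -> tuple[float, float]:
        return float(self.mean), float(self.sd)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size)


@dataclass(frozen=True)
class GammaDeleteriousDFE(DFESpec):
    """Purely deleterious: effects are minus a Gamma(shape, scale) draw."""

    shape: float = 2.0
    scale: float = 0.01
    family: str = "gamma_deleterious"

    def mean_sd(self) -> tuple[float, float]:
        return -self.shape * self.scale, np.sqrt(self.shape) * self.scale

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return -rng.gamma(self.shape, self.scale, size)


@dataclass(frozen=True)
class ReflectedGammaDFE(DFESpec):
    """Purely beneficial: effects are a Gamma(shape, scale) draw."""

    shape: float = 2.0
    scale: float = 0.01
    family: str = "reflected_gamma"

    def mean_sd(self) -> tuple[float, float]:
        return self.shape * self.scale, np.sqrt(self.shape) * self.scale

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size)


@dataclass(frozen=True)
class TwoComponentMixtureDFE(DFESpec):
    """Mixture of two normals, e.g. a deleterious bulk plus a beneficial tail.

    ``weight`` is the probability of the first component.
    """

    weight: float = 0.5
    mean1: float = -0.01
    sd1: float = 0.005
    mean2: float = 0.01
    sd2: float = 0.005
    family: str = "two_component_mixture"

    def mean_sd(self) -> tuple[float, float]:
        w = self.weight
        m = w * self.mean1 + (1 - w) * self.mean2
        second = w * (self.mean1 ** 2 + self.sd1 ** 2) + (1 - w) * (
            self.mean2 ** 2 + self.sd2 ** 2
        )
        return m, float(np.sqrt(second - m ** 2))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        pick = rng.random(size) < self.weight
        out = np.where(
            pick,
            rng.normal(self.mean1, self.sd1, size),
            rng.normal(self.mean2, self.sd2, size),
        )
        return out


_FAMILIES = {
    "point_mass": PointMassDFE,
    "normal": NormalDFE,
    "gamma_deleterious": GammaDeleteriousDFE,
    "reflected_gamma": ReflectedGammaDFE,
    "two_component_mixture": TwoComponentMixtureDFE,
}


def dfe_from_dict(d: dict[str, Any]) -> DFESpec:
    """Reconstruct a DFE spec from a plain dict (e.g. parsed YAML)."""
    d = dict(d)
    family = d.pop("family")
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(f"unknown DFE family {family!r}; known: {sorted(_FAMILIES)}")
    return cls(**d)
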