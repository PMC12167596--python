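"""Synthetic-experiment generator mirroring the EMS breeding design.

The generative model reproduces the field experiment's structure: six
founder accessions, two of which (high- and low-fitness focal ecotypes)
carry EMS-mutagenized lines.  Each mutant line descends from a single
mutagenized M1 seed, selfs to M2 (one plant whose dosage realization is
shared by the whole line), splits into two M3 sublines, and selfs once
more to the M4 plants scored in the field.  A plant's latent genetic score

    s = y + m + h + b

(founder value + subline maternal effect + mutational deviation + block
effect, all log10 mg) drives logistic survival p = 1/(1 + exp(c*s + d)),
and survivors get dry weight 10^(s + eps) with Normal(0, eta^2) residual
noise.  Dead plants score 0 mg.

The default configuration is the study design itself: 20 and 16 EMS lines
of 2 sublines x 60 plants for the focal founders, 120-plant controls for
all six founders, 12 blocks, Poisson(25) mutations per line, three selfing
generations, and a survival curve solved from the two focal founders'
control survival rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .dfe import DFESpec, NormalDFE, dfe_from_dict
from .io import ExperimentTable
from .moments import _transition

__all__ = [
    "FounderSpec",
    "SimulationConfig",
    "calibrate_survival",
    "default_config",
    "sample_dosage_path",
    "simulate_line",
    "simulate_experiment",
    "simulate_h_components",
    "config_from_yaml",
    "config_to_yaml",
]


@dataclass(frozen=True)
class FounderSpec:
    """One founder accession: its genetic value and design slice."""

    founder_id: str
    genetic_value: float  # y, log10 mg
    n_ems_lines: int = 0
    n_control_plants: int = 120
    noise_sd: float = 0.3  # eta, founder-specific residual SD (log10 mg)
    dfe: DFESpec | None = None  # required if n_ems_lines > 0


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative specification of a synthetic experiment."""

    founders: tuple[FounderSpec, ...]
    lambda_mut: float = 25.0  # mean mutations per EMS line
    n_sublines: int = 2
    n_per_subline: int = 60
    n_blocks: int = 12
    maternal_sd: float = 0.02  # log10 mg
    block_sd: float = 0.02  # log10 mg
    survival_c: float = -0.91281
    survival_d: float = 2.59436
    selfing_generations: int = 3
    block_assignment: str = "round_robin"  # or "random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_mut <= 0:
            raise ValueError("lambda_mut must be positive")
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        if self.maternal_sd < 0 or self.block_sd < 0:
            raise ValueError("effect SDs must be non-negative")
        for f in self.founders:
            if f.noise_sd <= 0:
                raise ValueError(f"noise_sd must be positive for {f.founder_id}")
            if f.n_ems_lines > 0 and f.dfe is None:
                raise ValueError(f"founder {f.founder_id} has EMS lines but no DFE")
        if self.block_assignment not in ("round_robin", "random"):
            raise ValueError("block_assignment must be 'round_robin' or 'random'")
        if any(f.n_ems_lines > 0 for f in self.founders) and self.selfing_generations < 3:
            # line shares M2, sublines share M3, individuals are M4 or later
            raise ValueError("EMS lines require selfing_generations >= 3")


def calibrate_survival(
    y1: float, p1: float, y2: float, p2: float
) -> tuple[float, float]:
    """Solve (c, d) of p = 1/(1 + exp(c*y + d)) through two (y, p) points.

    c comes out negative when the higher genetic value has the higher
    survival, matching the printed parameterization.
    """
    t1 = np.log((1 - p1) / p1)
    t2 = np.log((1 - p2) / p2)
    c = (t1 - t2) / (y1 - y2)
    d = t1 - c * y1
    return float(c), float(d)


# Published posterior-mean point estimates used as the default generative truth.
_POINT_ESTIMATES = {
    "COL": dict(y=2.886, mu=0.001, sigma=0.011, eta=0.208, n_ems=20),
    "CV": dict(y=2.164, mu=0.004, sigma=0.015, eta=0.327, n_ems=16),
    "28051": dict(y=2.298, eta=0.762, n_ems=0),
    "28364": dict(y=3.125, eta=0.074, n_ems=0),
    "28510": dict(y=3.109, eta=0.218, n_ems=0),
    "76197": dict(y=2.941, eta=0.215, n_ems=0),
}

# Control survival of the two focal founders pins the logistic curve.
_DEFAULT_C, _DEFAULT_D = calibrate_survival(2.886, 0.51, 2.164, 0.35)


def default_config(seed: int = 0) -> SimulationConfig:
    """The study design with the published point estimates as generative truth.

    Six founders; COL and CV carry 20 and 16 EMS lines (2 sublines x 60
    plants each) plus 120-plant controls; the other four founders are
    control-only (120 plants); 12 blocks; normal DFEs at the fitted
    (mu, sigma); survival curve solved from the two focal founders'
    control survival rates (0.51 and 0.35).
    """
    founders = []
    for fid, p in _POINT_ESTIMATES.items():
        dfe = None
        if p["n_ems"] > 0:
            dfe = NormalDFE(mean=p["mu"], sd=p["sigma"])
        founders.append(
            FounderSpec(
                founder_id=fid,
                genetic_value=p["y"],
                n_ems_lines=p["n_ems"],
                n_control_plants=120,
                noise_sd=p["eta"],
                dfe=dfe,
            )
        )
    return SimulationConfig(
        founders=tuple(founders),
        survival_c=_DEFAULT_C,
        survival_d=_DEFAULT_D,
        seed=seed,
    )


def sample_dosage_path(g: int, rng: np.random.Generator) -> np.ndarray:
    """Dosage of one mutation after each of ``g`` selfing generations.

    Starts heterozygous (dosage 1) in M1; returns the length-``g`` sequence
    of dosages in M2..M(g+1).
    """
    if g < 1:
        raise ValueError(f"selfing generations must be >= 1, got {g}")
    path = np.empty(g, dtype=np.int64)
    d = np.ones(1, dtype=np.int64)
    for i in range(g):
        d = _transition(d, rng)
        path[i] = d[0]
    return path


def _simulate_group(
    founder: FounderSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    line_id: str,
    ems: bool,
    n_sublines: int,
    n_per_subline: int,
    block_cycle: "_BlockCycle",
    block_effects: np.ndarray,
) -> pd.DataFrame:
    """Simulate one line (mutant or control): all its sublines and plants."""
    g = config.selfing_generations
    n_plants = n_sublines * n_per_subline
    if ems:
        n_mut = rng.poisson(config.lambda_mut)
        effects = founder.dfe.sample(rng, n_mut)
        # one M2 dosage realization shared by the whole line
        m2 = _transition(np.ones(n_mut, dtype=np.int64), rng)
    else:
        n_mut = 0
        effects = np.zeros(0)
        m2 = np.zeros(0, dtype=np.int64)

    rows = []
    for k in range(n_sublines):
        maternal = rng.normal(0.0, config.maternal_sd)
        if ems:
            m3 = _transition(m2, rng)  # one M3 parent per subline
        for _ in range(n_per_subline):
            if ems:
                dosage = m3
                for _ in range(g - 2):  # M3 -> M4 (and beyond for larger g)
                    dosage = _transition(dosage, rng)
                h = float(dosage @ effects) if n_mut else 0.0
            else:
                h = 0.0
            block = block_cycle.next(rng)
            s = founder.genetic_value + maternal + h + block_effects[block]
            p_surv = 1.0 / (1.0 + np.exp(config.survival_c * s + config.survival_d))
            survived = rng.random() < p_surv
            if survived:
                weight = 10.0 ** (s + rng.normal(0.0, founder.noise_sd))
            else:
                weight = 0.0
            rows.append(
                (
                    founder.founder_id,
                    line_id,
                    str(k + 1),
                    str(block + 1),
                    ems,
                    bool(survived),
                    weight,
                )
            )
    assert len(rows) == n_plants
    return pd.DataFrame(
        rows,
        columns=[
            "founder_id",
            "line_id",
            "subline_id",
            "block_id",
            "ems_treated",
            "survived",
            "dry_weight_mg",
        ],
    )


class _BlockCycle:
    """Assign plants to blocks round-robin (balanced) or at random."""

    def __init__(self, n_blocks: int, mode: str) -> None:
        self.n_blocks = n_blocks
        self.mode = mode
        self._i = 0

    def next(self, rng: np.random.Generator) -> int:
        if self.mode == "random":
            return int(rng.integers(self.n_blocks))
        b = self._i % self.n_blocks
        self._i += 1
        return b


def simulate_line(
    founder: FounderSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    line_id: str = "L01",
) -> pd.DataFrame:
    """Plant records for a single EMS line (all sublines) of ``founder``."""
    if founder.dfe is None:
        raise ValueError("simulate_line requires a founder with a DFE")
    block_effects = rng.normal(0.0, config.block_sd, config.n_blocks)
    cycle = _BlockCycle(config.n_blocks, config.block_assignment)
    return _simulate_group(
        founder,
        config,
        rng,
        line_id,
        ems=True,
        n_sublines=config.n_sublines,
        n_per_subline=config.n_per_subline,
        block_cycle=cycle,
        block_effects=block_effects,
    )


def simulate_experiment(config: SimulationConfig) -> ExperimentTable:
    """Generate the full experiment table; deterministic given the seed.

    One master seed; per-line substreams are spawned deterministically so
    the realization of any one line does not depend on how many plants the
    previous lines produced.
    """
    master = np.random.SeedSequence(config.seed)
    top_rng = np.random.default_rng(master.spawn(1)[0])
    block_effects = top_rng.normal(0.0, config.block_sd, config.n_blocks)
    cycle = _BlockCycle(config.n_blocks, config.block_assignment)

    units: list[tuple[FounderSpec, str, bool, int, int]] = []
    for f in config.founders:
        if f.n_control_plants > 0:
            n_sub = min(config.n_sublines, f.n_control_plants)
            per = f.n_control_plants // n_sub
            units.append((f, "control", False, n_sub, per))
        width = max(2, len(str(f.n_ems_lines)))
        for j in range(f.n_ems_lines):
            units.append((f, f"L{j + 1:0{width}d}", True, config.n_sublines,
                          config.n_per_subline))

    streams = master.spawn(len(units) + 1)[1:]
    frames = []
    for (f, line_id, ems, n_sub, per), ss in zip(units, streams):
        rng = np.random.default_rng(ss)
        frames.append(
            _simulate_group(f, config, rng, line_id, ems, n_sub, per, cycle,
                            block_effects)
        )
    df = pd.concat(frames, ignore_index=True)
    return ExperimentTable(df)


def simulate_h_components(
    n_lines: int,
    lambda_mut: float,
    dfe: DFESpec,
    rng: np.random.Generator,
    g: int = 3,
) -> dict[str, np.ndarray]:
    """Vectorized h draws for many lines, exposing the pedigree structure.

    For each of ``n_lines`` independent lines, returns h for three plants:
    two from subline 1 (``a1``, ``a2``) and one from subline 2 (``b1``),
    all with the M2 dosage realization shared within the line.  Used as the
    Monte Carlo oracle for the line/subline/individual covariance split.
    Requires g >= 3 (M2 shared by line, M3 by subline).
    """
    if g < 3:
        raise ValueError("component oracle needs g >= 3")
    counts = rng.poisson(lambda_mut, n_lines)
    total = int(counts.sum())
    owner = np.repeat(np.arange(n_lines), counts)
    effects = dfe.sample(rng, total)
    m2 = _transition(np.ones(total, dtype=np.int64), rng)
    m3_s1 = _transition(m2, rng)
    m3_s2 = _transition(m2, rng)

    def descend(m3: np.ndarray) -> np.ndarray:
        d = m3
        for _ in range(g - 2):
            d = _transition(d, rng)
        return d

    out = {}
    for name, m3 in (("a1", m3_s1), ("a2", m3_s1), ("b1", m3_s2)):
        dosage = descend(m3)
        out[name] = np.bincount(owner, weights=dosage * effects, minlength=n_lines)
    return out


# ---------------------------------------------------------------------------
# YAML round-trip for configs


def _founder_to_dict(f: FounderSpec) -> dict[str, Any]:
    d: dict[str, Any] = {
        "founder_id": f.founder_id,
        "genetic_value": f.genetic_value,
        "n_ems_lines": f.n_ems_lines,
        "n_control_plants": f.n_control_plants,
        "noise_sd": f.noise_sd,
    }
    if f.dfe is not None:
        d["dfe"] = {"family": f.dfe.family, **{k: v for k, v in f.dfe.to_dict().items()
                                               if k != "family"}}
    return d


def config_to_yaml(config: SimulationConfig, path: str | Path) -> None:
    d = {
        "founders": [_founder_to_dict(f) for f in config.founders],
        "lambda_mut": config.lambda_mut,
        "n_sublines": config.n_sublines,
        "n_per_subline": config.n_per_subline,
        "n_blocks": config.n_blocks,
        "maternal_sd": config.maternal_sd,
        "block_sd": config.block_sd,
        "survival_c": config.survival_c,
        "survival_d": config.survival_d,
        "selfing_generations": config.selfing_generations,
        "block_assignment": config.block_assignment,
        "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def config_from_yaml(path: str | Path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    founders = []
    for fd in d.pop("founders"):
        dfe = fd.pop("dfe", None)
        founders.append(FounderSpec(dfe=dfe_from_dict(dfe) if dfe else None, **fd))
    return SimulationConfig(founders=tuple(founders), **d)
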