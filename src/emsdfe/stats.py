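"""Descriptive statistics and classical tests on experiment tables.

Covers the summary-table style group summaries (survival rate; log10 weight among
survivors), Dunnett-type many-to-one comparisons of mutant lines against
the unmutated control, a count of lines whose mean fitness exceeds the
control, and Fisher's exact test on albino silique counts.

"Fitness" for comparisons that include dead plants is the zero-inflated
score used by the model: 0 for a dead plant, log10 dry weight (mg) for a
survivor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExperimentTable

__all__ = [
    "group_summaries",
    "fitness_scores",
    "compare_lines_to_control",
    "count_lines_above_control",
    "albino_fisher_test",
]


def fitness_scores(table: ExperimentTable) -> pd.Series:
    """Zero-inflated fitness score per plant: 0 if dead, log10 mg if alive."""
    z = table.log10_weight.fillna(0.0)
    return z.rename("fitness")


def group_summaries(
    table: ExperimentTable, grouping: str = "treatment"
) -> pd.DataFrame:
    """Per-group seedling counts, survival rate, and survivor weight stats.

    ``grouping`` is ``"treatment"`` (founder x control/EMS, the summary-table
    layout) or ``"line"`` (founder x line).  Mean and SD of log10 weight are
    computed over survivors only; the SD is NaN for fewer than two
    survivors.
    """
    df = table.df.copy()
    df["log10_weight"] = table.log10_weight
    if grouping == "treatment":
        df["treatment"] = np.where(df["ems_treated"], "EMS", "control")
        keys = ["founder_id", "treatment"]
    elif grouping == "line":
        keys = ["founder_id", "line_id"]
    else:
        raise ValueError("grouping must be 'treatment' or 'line'")

    def agg(gr: pd.DataFrame) -> pd.Series:
        alive = gr["survived"]
        zs = gr.loc[alive, "log10_weight"]
        return pd.Series({
            "n_seedlings": len(gr),
            "n_survived": int(alive.sum()),
            "survival_rate": alive.mean(),
            "mean_log10_weight": zs.mean() if len(zs) else np.nan,
            "sd_log10_weight": zs.std(ddof=1) if len(zs) >= 2 else np.nan,
        })

    out = df.groupby(keys, sort=False).apply(agg, include_groups=False).reset_index()
    out["n_seedlings"] = out["n_seedlings"].astype(int)
    out["n_survived"] = out["n_survived"].astype(int)
    return out


def _line_samples(
    table: ExperimentTable, founder: str, survivors_only: bool
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    df = table.df[table.df["founder_id"] == founder]
    if df.empty:
        raise ValueError(f"no plants for founder {founder!r}")
    scores = fitness_scores(table).loc[df.index]
    if survivors_only:
        keep = df["survived"].to_numpy(dtype=bool)
        df = df[keep]
        scores = scores[keep]
    control = scores[~df["ems_treated"]].to_numpy()
    if control.size == 0:
        raise ValueError(f"founder {founder!r} has no control plants")
    lines = {}
    for line_id, gr in df[df["ems_treated"]].groupby("line_id", sort=False):
        lines[line_id] = scores.loc[gr.index].to_numpy()
    if not lines:
        raise ValueError(f"founder {founder!r} has no mutant lines")
    return control, lines


def compare_lines_to_control(
    table: ExperimentTable,
    founder: str,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Dunnett many-to-one comparison of each mutant line against the control.

    Two passes mirror the published analysis: ``with_zeros`` compares the
    zero-inflated fitness scores of all plants, ``survivors_only`` repeats
    the comparison on surviving plants' log10 weights.  Family-wise error is
    controlled by the exact multivariate-t Dunnett procedure
    (``scipy.stats.dunnett``); adjusted p-values are reported per line.
    ``alternative="greater"`` asks whether a line outperforms the control.
    """
    frames = []
    for pass_name, survivors_only in (("with_zeros", False), ("survivors_only", True)):
        control, lines = _line_samples(table, founder, survivors_only)
        usable = {k: v for k, v in lines.items() if len(v) >= 2}
        if len(control) < 2 or not usable:
            continue
        res = sps.dunnett(*usable.values(), control=control, alternative=alternative)
        frames.append(pd.DataFrame({
            "pass": pass_name,
            "line_id": list(usable.keys()),
            "n": [len(v) for v in usable.values()],
            "mean_diff": [v.mean() - control.mean() for v in usable.values()],
            "statistic": res.statistic,
            "pvalue_adj": res.pvalue,
            "method": "dunnett_mvt",
        }))
    if not frames:
        raise ValueError("no comparable lines (need >= 2 plants per group)")
    return pd.concat(frames, ignore_index=True)


def count_lines_above_control(
    table: ExperimentTable, founder: str, include_zeros: bool = True
) -> int:
    """Number of mutant lines whose mean fitness exceeds the control mean.

    With ``include_zeros`` (default) dead plants count as fitness 0,
    matching the zero-inflated fitness measure; otherwise means are over
    survivors only.
    """
    control, lines = _line_samples(table, founder, survivors_only=not include_zeros)
    cmean = control.mean()
    return int(sum(v.mean() > cmean for v in lines.values() if len(v)))


def albino_fisher_test(a: int, n_a: int, b: int, n_b: int) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table of albino siliques.

    The table is [[a, n_a - a], [b, n_b - b]].  Computed by direct
    enumeration of the hypergeometric distribution with fixed margins: the
    p-value sums the probabilities of all tables no more probable than the
    observed one.
    """
    for name, (x, n) in {"first": (a, n_a), "second": (b, n_b)}.items():
        if not 0 <= x <= n:
            raise ValueError(f"invalid counts in {name} group: {x} out of {n}")
    total = n_a + n_b
    successes = a + b
    support = np.arange(max(0, successes - n_b), min(successes, n_a) + 1)
    pmf = sps.hypergeom.pmf(support, total, successes, n_a)
    observed = sps.hypergeom.pmf(a, total, successes, n_a)
    # relative tolerance guards against ties broken by floating-point noise
    p = float(pmf[pmf <= observed * (1 + 1e-9)].sum())
    return min(p, 1.0)
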