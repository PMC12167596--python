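"""Dosage-moment and compound-Poisson machinery for selfing pedigrees.

A new heterozygous mutation in an M1 plant follows a three-state Markov
chain under selfing: dosage ``n in {0, 1, 2}`` with transitions from the
segregating state 1 to ``{0: 1/4, 1: 1/2, 2: 1/4}`` and absorbing loss/
fixation states.  The total mutational deviation of a plant,

    h = sum_m n_m * e_m,   P ~ Poisson(lambda),  e_m ~ DFE,

is a compound Poisson variable whose first two moments — and the
line/subline/individual covariance split induced by the shared pedigree —
are exact rational functions of the dosage moments.  Everything here is
computed by enumeration over the chain, with the closed forms
``E[n] = 1`` and ``E[n^2] = 2 - 2^(-g)`` available as cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .dfe import DFESpec

__all__ = [
    "DosageMoments",
    "CompoundPoissonMoments",
    "dosage_distribution",
    "dosage_moments",
    "compound_poisson_moments",
    "sample_compound_poisson",
    "CLTDiagnostic",
    "clt_diagnostic",
]


def dosage_distribution(g: int) -> dict[int, Fraction]:
    """Exact distribution of dosage after ``g`` selfing generations.

    Starts from a single heterozygote (dosage 1); returns the probability of
    each dosage state as an exact rational.
    """
    if g < 1:
        raise ValueError(f"selfing generations must be >= 1, got {g}")
    p = {0: Fraction(0), 1: Fraction(1), 2: Fraction(0)}
    for _ in range(g):
        seg = p[1]
        p = {
            0: p[0] + seg * Fraction(1, 4),
            1: seg * Fraction(1, 2),
            2: p[2] + seg * Fraction(1, 4),
        }
    return p


@dataclass(frozen=True)
class DosageMoments:
    """Exact moments of mutant-allele dosage under ``g`` selfing generations."""

    g: int
    first: Fraction
    second: Fraction

    def cross_moment(self, g_shared: int) -> Fraction:
        """E[n n'] for two descendants whose pedigrees merge at ``g_shared``.

        Conditional on the shared ancestor's dosage the two branches are
        independent, and dosage is a martingale (``E[n_child | n] = n``),
        so the cross moment equals the ancestor's second moment.
        """
        if not 1 <= g_shared <= self.g:
            raise ValueError(f"g_shared must be in [1, {self.g}], got {g_shared}")
        return dosage_moments(g_shared).second

    @property
    def heterozygosity(self) -> Fraction:
        """Probability the mutation still segregates (dosage 1)."""
        return dosage_distribution(self.g)[1]

    @property
    def homozygosity(self) -> Fraction:
        """Probability the mutation is fixed or lost (dosage 0 or 2)."""
        return 1 - self.heterozygosity


def dosage_moments(g: int) -> DosageMoments:
    """First and second dosage moments by exact chain enumeration.

    Satisfies ``E[n] = 1`` for all g and ``E[n^2] = 2 - 2^(-g)``.
    """
    dist = dosage_distribution(g)
    first = sum(n * p for n, p in dist.items())
    second = sum(n * n * p for n, p in dist.items())
    return DosageMoments(g=g, first=first, second=second)


@dataclass(frozen=True)
class CompoundPoissonMoments:
    """Moments of h = sum n_m e_m and its pedigree covariance split.

    ``line_var`` is the variance of the component shared by the whole line
    (mutations whose dosage was already decided in the single M2 plant);
    ``subline_var`` adds the covariance increment from the shared M3 parent
    of a subline; ``individual_var`` is the residual individual-specific
    part.  The three sum exactly to ``variance``.  The mean ``lambda * mu``
    is carried entirely by the line-level component.
    """

    lambda_mut: float
    mu: float
    sigma: float
    g: int
    mean: float
    variance: float
    line_var: float
    subline_var: float
    individual_var: float


def compound_poisson_moments(
    lambda_mut: float, mu: float, sigma: float, g: int = 3
) -> CompoundPoissonMoments:
    """Mean, total variance, and line/subline/individual variance split.

    For a compound Poisson sum over dosages, ``E[h] = lambda * mu`` and
    ``Var(h) = E[n^2] * lambda * (mu^2 + sigma^2)``; with g = 3 the split is
    1.5 : 0.25 : 0.125 times ``lambda (mu^2 + sigma^2)``, totalling 1.875.
    The split assumes the two sublines descend from one M2 plant (shared
    generation 1) and individuals share their subline's M3 parent
    (shared generation 2).
    """
    if lambda_mut <= 0:
        raise ValueError("lambda_mut must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    dm = dosage_moments(g)
    q = lambda_mut * (mu ** 2 + sigma ** 2)
    total = float(dm.second) * q
    if g >= 2:
        c_line = float(dm.cross_moment(1))
        c_sub = float(dm.cross_moment(2))
    else:  # no subline split possible with a single generation
        c_line = c_sub = float(dm.second)
    return CompoundPoissonMoments(
        lambda_mut=lambda_mut,
        mu=mu,
        sigma=sigma,
        g=g,
        mean=lambda_mut * mu,
        variance=total,
        line_var=c_line * q,
        subline_var=(c_sub - c_line) * q,
        individual_var=(float(dm.second) - c_sub) * q,
    )


def _transition(dosage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One selfing generation applied elementwise to a dosage array."""
    out = dosage.copy()
    seg = dosage == 1
    n_seg = int(seg.sum())
    if n_seg:
        u = rng.random(n_seg)
        out[seg] = np.searchsorted([0.25, 0.75], u)  # 0, 1 or 2
    return out


def sample_final_dosage(g: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized Monte Carlo of the dosage chain: final dosages of ``size`` paths."""
    if g < 1:
        raise ValueError(f"selfing generations must be >= 1, got {g}")
    dosage = np.ones(size, dtype=np.int64)
    for _ in range(g):
        dosage = _transition(dosage, rng)
    return dosage


def sample_compound_poisson(
    lambda_mut: float,
    dfe: DFESpec,
    g: int,
    n_draws: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Brute-force draws of h for independent plants (oracle sampler).

    Each draw gets its own Poisson mutation count, iid effects from the DFE,
    and an independent dosage path per mutation.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    counts = rng.poisson(lambda_mut, n_draws)
    total = int(counts.sum())
    if total == 0:
        return np.zeros(n_draws)
    effects = dfe.sample(rng, total)
    dosages = sample_final_dosage(g, total, rng)
    owner = np.repeat(np.arange(n_draws), counts)
    return np.bincount(owner, weights=dosages * effects, minlength=n_draws)


@dataclass(frozen=True)
class CLTDiagnostic:
    """Result of the normality diagnostic for standardized h."""

    statistic: float  # Kolmogorov-Smirnov distance to N(0,1)
    threshold: float  # calibrated on same-size exact-normal samples
    null_mean: float
    null_sd: float
    passed: bool


def _standardized_ks(x: np.ndarray) -> float:
    z = (x - x.mean()) / x.std()
    return float(stats.kstest(z, "norm").statistic)


def clt_diagnostic(
    lambda_mut: float,
    dfe: DFESpec,
    g: int,
    n_draws: int,
    rng: np.random.Generator,
    n_calibration: int = 200,
    quantile: float = 0.999,
) -> CLTDiagnostic:
    """Distance between standardized h and a standard normal, with a
    Monte Carlo calibrated pass threshold.

    The statistic is the Kolmogorov-Smirnov distance of the standardized h
    sample to N(0,1).  The threshold is the ``quantile`` of the same
    statistic over ``n_calibration`` exact-normal samples of the same size
    (standardized the same way), so "passed" means the sample is not
    distinguishable from normal beyond what estimation noise at this sample
    size produces at that quantile.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10^4 for a stable diagnostic")
    h = sample_compound_poisson(lambda_mut, dfe, g, n_draws, rng)
    stat = _standardized_ks(h)
    null = np.array(
        [_standardized_ks(rng.standard_normal(n_draws)) for _ in range(n_calibration)]
    )
    thr = float(np.quantile(null, quantile))
    return CLTDiagnostic(
        statistic=stat,
        threshold=thr,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        passed=bool(stat < thr),
    )
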