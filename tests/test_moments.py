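from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emsdfe import (
    GammaDeleteriousDFE,
    NormalDFE,
    PointMassDFE,
    ReflectedGammaDFE,
    TwoComponentMixtureDFE,
    compound_poisson_moments,
    dosage_distribution,
    dosage_moments,
    sample_compound_poisson,
)
from emsdfe.moments import sample_final_dosage

ALL_DFES = [
    PointMassDFE(effect=0.1),
    NormalDFE(mean=0.004, sd=0.015),
    GammaDeleteriousDFE(shape=2.0, scale=0.01),
    ReflectedGammaDFE(shape=2.0, scale=0.01),
    TwoComponentMixtureDFE(weight=0.7, mean1=-0.01, sd1=0.004,
                           mean2=0.02, sd2=0.008),
]


class TestDosageMoments:
    def test_one_generation_exact(self):
        dm = dosage_moments(1)
        assert dm.first == 1
        assert dm.second == Fraction(3, 2)

    @pytest.mark.parametrize("g", range(1, 9))
    def test_closed_form_cross_check(self, g):
        # enumeration must reproduce E[n] = 1 and E[n^2] = 2 - 2^(-g)
        dm = dosage_moments(g)
        assert dm.first == 1
        assert dm.second == 2 - Fraction(1, 2 ** g)

    def test_second_moment_increases_toward_two(self):
        seconds = [dosage_moments(g).second for g in range(1, 8)]
        assert all(a < b for a, b in zip(seconds, seconds[1:]))
        assert all(s < 2 for s in seconds)

    def test_cross_moment_is_shared_ancestor_second_moment(self):
        dm = dosage_moments(3)
        assert dm.cross_moment(1) == Fraction(3, 2)
        assert dm.cross_moment(2) == Fraction(7, 4)
        assert dm.cross_moment(3) == dm.second

    def test_heterozygosity_halves_each_generation(self):
        for g in range(1, 6):
            assert dosage_distribution(g)[1] == Fraction(1, 2 ** g)

    def test_invalid_generations(self):
        with pytest.raises(ValueError):
            dosage_moments(0)

    def test_monte_carlo_agrees_with_enumeration(self, rng):
        for g in (1, 2, 3, 4):
            n = sample_final_dosage(g, 200_000, rng).astype(float)
            second = float(dosage_moments(g).second)
            se = (n ** 2).std() / np.sqrt(len(n))
            assert abs((n ** 2).mean() - second) < 4 * se


class TestCompoundPoissonMoments:
    def test_printed_variance_coefficient(self):
        cp = compound_poisson_moments(25, 0.0, 0.015, g=3)
        assert cp.mean == 0.0
        assert np.isclose(cp.variance, 1.875 * 25 * 0.015 ** 2)
        assert np.isclose(cp.variance, 0.010546875)

    def test_degenerate_dfe_has_zero_variance(self):
        cp = compound_poisson_moments(25, 0.0, 0.0, g=3)
        assert cp.variance == cp.line_var == cp.subline_var == 0.0

    def test_three_generation_split_ratios(self):
        cp = compound_poisson_moments(25, 0.004, 0.015, g=3)
        q = 25 * (0.004 ** 2 + 0.015 ** 2)
        assert np.isclose(cp.line_var, 1.5 * q)
        assert np.isclose(cp.subline_var, 0.25 * q)
        assert np.isclose(cp.individual_var, 0.125 * q)

    @given(
        lam=st.floats(0.1, 100),
        mu=st.floats(-0.05, 0.05),
        sigma=st.floats(0, 0.05),
        g=st.integers(2, 8),
    )
    @settings(max_examples=60, deadline=None)
    def test_components_sum_to_total(self, lam, mu, sigma, g):
        cp = compound_poisson_moments(lam, mu, sigma, g)
        total = cp.line_var + cp.subline_var + cp.individual_var
        assert np.isclose(total, cp.variance, rtol=1e-12, atol=1e-15)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            compound_poisson_moments(0.0, 0.0, 0.01)
        with pytest.raises(ValueError):
            compound_poisson_moments(25, 0.0, -0.01)


class TestSampler:
    @pytest.mark.parametrize("dfe", ALL_DFES, ids=lambda d: d.family)
    def test_empirical_moments_match_closed_form(self, dfe, rng):
        lam, g, n = 25.0, 3, 60_000
        h = sample_compound_poisson(lam, dfe, g, n, rng)
        mu, sigma = dfe.mean_sd()
        cp = compound_poisson_moments(lam, mu, sigma, g)
        se_mean = h.std() / np.sqrt(n)
        assert abs(h.mean() - cp.mean) < 4 * se_mean
        # variance of the sample variance via fourth-moment estimate
        c = h - h.mean()
        se_var = np.sqrt(((c ** 2 - c.var()) ** 2).mean() / n)
        assert abs(h.var() - cp.variance) < 4 * se_var

    def test_atom_at_zero_for_rare_mutations(self, rng):
        # P(h = 0) = exp(-lambda * P(dosage > 0)) = exp(-lambda * 9/16) at g=3
        lam = 0.1
        h = sample_compound_poisson(lam, PointMassDFE(effect=0.1), 3, 200_000, rng)
        p0 = (h == 0).mean()
        expected = np.exp(-lam * 9 / 16)
        assert abs(p0 - expected) < 4 * np.sqrt(expected * (1 - expected) / 200_000)

    def test_law_of_large_numbers_point_mass(self, rng):
        h = sample_compound_poisson(400.0, PointMassDFE(effect=0.05), 3, 4_000, rng)
        # h / lambda -> e0 * E[n] = e0
        assert abs(h.mean() / 400.0 - 0.05) < 0.001


@pytest.mark.parametrize("dfe", ALL_DFES, ids=lambda d: d.family)
def test_dfe_closed_form_moments_match_sampling(dfe, rng):
    x = dfe.sample(rng, 200_000)
    mu, sigma = dfe.mean_sd()
    assert abs(x.mean() - mu) < 5 * max(sigma, 1e-9) / np.sqrt(len(x)) + 1e-12
    assert np.isclose(x.std(), sigma, rtol=0.02, atol=1e-9)
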