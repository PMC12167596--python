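import warnings

import numpy as np
import pandas as pd
import pytest

from emsdfe import (
    ExperimentTable,
    FounderSpec,
    ModelConfig,
    NormalDFE,
    SimulationConfig,
    build_model,
    fit_variational,
    posterior_credible_check,
    simulate_experiment,
)
from emsdfe.model import PosteriorSummary

FAST = ModelConfig(max_iter=1500, min_iter=400, n_draws=500, seed=3)


@pytest.fixture(scope="module")
def small_fit(small_table_module):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cfg = ModelConfig(max_iter=6000, min_iter=1500, seed=3)
        return fit_variational(build_model(small_table_module, cfg))


@pytest.fixture(scope="module")
def small_table_module():
    founders = (
        FounderSpec("alpha", 2.8, n_ems_lines=4, n_control_plants=40,
                    noise_sd=0.2, dfe=NormalDFE(mean=0.003, sd=0.012)),
        FounderSpec("beta", 2.3, n_ems_lines=0, n_control_plants=40,
                    noise_sd=0.3),
    )
    cfg = SimulationConfig(founders=founders, n_per_subline=10, n_blocks=4,
                           seed=7)
    return simulate_experiment(cfg)


def test_gradient_matches_finite_differences(small_table_module, rng):
    model = build_model(small_table_module, ModelConfig())
    th = model.init_loc() + 0.2 * rng.standard_normal(model.dim)
    _, grad = model.logp_and_grad(th)
    for i in rng.choice(model.dim, size=min(50, model.dim), replace=False):
        tp, tm = th.copy(), th.copy()
        tp[i] += 1e-6
        tm[i] -= 1e-6
        fd = (model.logp_and_grad(tp)[0] - model.logp_and_grad(tm)[0]) / 2e-6
        assert abs(fd - grad[i]) / (1 + abs(fd)) < 1e-5


def test_fit_is_deterministic_given_seed(small_table_module):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = fit_variational(build_model(small_table_module, FAST))
        b = fit_variational(build_model(small_table_module, FAST))
    for k in a.params:
        assert a.params[k].mean == b.params[k].mean
        assert a.params[k].ci95 == b.params[k].ci95


def test_control_only_table_has_no_dfe_parameters():
    founders = (FounderSpec("solo", 2.5, n_control_plants=60, noise_sd=0.2),)
    tab = simulate_experiment(SimulationConfig(founders=founders, n_blocks=4,
                                               seed=1))
    model = build_model(tab, ModelConfig())
    assert model.Ff == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_variational(model, FAST)
    assert not any(k.startswith(("mu[", "sigma[")) for k in fit.params)
    assert "y[solo]" in fit.params and "eta[solo]" in fit.params


def test_focal_founder_without_controls_warns():
    founders = (
        FounderSpec("x", 2.5, n_ems_lines=2, n_control_plants=0,
                    noise_sd=0.2, dfe=NormalDFE(0.0, 0.01)),
    )
    tab = simulate_experiment(SimulationConfig(founders=founders, n_blocks=4,
                                               seed=2))
    with pytest.warns(UserWarning, match="no control plants"):
        build_model(tab, ModelConfig())


class TestPosteriorSummary:
    def test_positive_scales_and_nested_intervals(self, small_fit):
        for k, p in small_fit.params.items():
            assert p.ci99[0] <= p.ci95[0] <= p.ci95[1] <= p.ci99[1]
            if k.startswith(("sigma[", "eta[")) or k.endswith("_sd"):
                assert p.ci99[0] > 0.0

    def test_parameter_inventory_matches_design(self, small_fit):
        names = set(small_fit.params)
        assert {"y[alpha]", "y[beta]", "mu[alpha]", "sigma[alpha]",
                "eta[alpha]", "eta[beta]", "maternal_sd", "block_sd",
                "c", "d"} <= names
        assert "mu[beta]" not in names  # beta was never mutagenized

    def test_larger_sample_narrows_genetic_value_posterior(self, small_fit):
        # alpha contributes 120 plants (EMS + control), beta only 40
        assert small_fit.params["y[beta]"].sd > small_fit.params["y[alpha]"].sd

    def test_recovers_generative_truth_roughly(self, small_fit):
        assert abs(small_fit.params["y[alpha]"].mean - 2.8) < 0.15
        assert abs(small_fit.params["eta[alpha]"].mean - 0.2) < 0.05

    def test_json_round_trip(self, small_fit, tmp_path):
        p = tmp_path / "summary.json"
        small_fit.to_json(p)
        back = PosteriorSummary.from_json(p)
        for k in small_fit.params:
            assert back.params[k].mean == pytest.approx(small_fit.params[k].mean)
        assert back.converged == small_fit.converged


class TestCredibleCheck:
    def test_outside_and_inside(self, small_fit):
        p = small_fit.params["y[alpha]"]
        mid = 0.5 * (p.ci95[0] + p.ci95[1])
        assert posterior_credible_check(small_fit, "y[alpha]", 0.95, mid) is False
        assert posterior_credible_check(small_fit, "y[alpha]", 0.95,
                                        p.ci95[1] + 1.0) is True

    def test_unknown_parameter_raises(self, small_fit):
        with pytest.raises(KeyError):
            posterior_credible_check(small_fit, "nope", 0.95, 0.0)
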