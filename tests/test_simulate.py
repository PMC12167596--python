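import numpy as np
import pytest

from emsdfe import (
    FounderSpec,
    NormalDFE,
    PointMassDFE,
    SimulationConfig,
    calibrate_survival,
    compound_poisson_moments,
    default_config,
    sample_dosage_path,
    simulate_experiment,
    simulate_h_components,
    simulate_line,
)
from emsdfe.simulate import config_from_yaml, config_to_yaml


class TestDosagePath:
    def test_single_generation_frequencies(self, rng):
        finals = np.array([sample_dosage_path(1, rng)[0] for _ in range(20_000)])
        freqs = np.bincount(finals, minlength=3) / len(finals)
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_absorbing_states(self, rng):
        for _ in range(300):
            path = sample_dosage_path(4, rng)
            for i in range(len(path) - 1):
                if path[i] in (0, 2):
                    assert path[i + 1] == path[i]

    def test_path_length_and_validation(self, rng):
        assert len(sample_dosage_path(5, rng)) == 5
        with pytest.raises(ValueError):
            sample_dosage_path(0, rng)


class TestSimulateExperiment:
    def test_study_design_record_count(self, study_table):
        assert len(study_table) == 5040
        assert study_table.df["block_id"].nunique() == 12

    def test_deterministic_given_seed(self):
        cfg = default_config(seed=123)
        assert simulate_experiment(cfg).equals(simulate_experiment(cfg))

    def test_different_seeds_differ(self):
        a = simulate_experiment(default_config(seed=1))
        b = simulate_experiment(default_config(seed=2))
        assert not a.equals(b)

    def test_ems_only_for_focal_founders(self, study_table):
        df = study_table.df
        ems_founders = set(df.loc[df["ems_treated"], "founder_id"])
        assert ems_founders == {"COL", "CV"}

    def test_control_survival_calibration(self, study_table):
        # COL control survival targeted 0.51; binomial error at n = 120
        df = study_table.df
        sel = (df["founder_id"] == "COL") & ~df["ems_treated"]
        rate = df.loc[sel, "survived"].mean()
        assert abs(rate - 0.51) < 4 * np.sqrt(0.51 * 0.49 / 120)

    def test_flat_logistic_gives_half_survival(self):
        founders = (FounderSpec("x", 2.5, n_control_plants=2000, noise_sd=0.2),)
        cfg = SimulationConfig(founders=founders, survival_c=0.0, survival_d=0.0,
                               n_blocks=4, seed=3)
        tab = simulate_experiment(cfg)
        assert abs(tab.df["survived"].mean() - 0.5) < 4 * np.sqrt(0.25 / 2000)

    def test_calibrate_survival_passes_through_points(self):
        c, d = calibrate_survival(2.886, 0.51, 2.164, 0.35)
        assert c < 0  # higher genetic value must mean higher survival
        for y, p in ((2.886, 0.51), (2.164, 0.35)):
            assert np.isclose(1 / (1 + np.exp(c * y + d)), p)

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = default_config(seed=9)
        p = tmp_path / "cfg.yaml"
        config_to_yaml(cfg, p)
        back = config_from_yaml(p)
        assert back == cfg


class TestGenerativeOracles:
    def test_zero_effect_mutations_leave_no_group_shift(self):
        founders = (
            FounderSpec("x", 2.5, n_ems_lines=12, n_control_plants=400,
                        noise_sd=0.1, dfe=PointMassDFE(effect=0.0)),
        )
        cfg = SimulationConfig(founders=founders, n_per_subline=30, n_blocks=4,
                               maternal_sd=0.0, block_sd=0.0, seed=21)
        tab = simulate_experiment(cfg)
        z = tab.log10_weight
        ems = tab.df["ems_treated"] & tab.df["survived"]
        ctrl = ~tab.df["ems_treated"] & tab.df["survived"]
        se = 0.1 * np.sqrt(1 / ems.sum() + 1 / ctrl.sum())
        assert abs(z[ems].mean() - z[ctrl].mean()) < 4 * se

    def test_line_h_mean_and_variance_match_compound_poisson(self, rng):
        # across many simulated lines the latent h obeys the CLT moments
        lam, dfe = 25.0, NormalDFE(mean=0.004, sd=0.015)
        comp = simulate_h_components(20_000, lam, dfe, rng)
        h = comp["a1"]
        cp = compound_poisson_moments(lam, *dfe.mean_sd(), g=3)
        assert abs(h.mean() - cp.mean) < 4 * h.std() / np.sqrt(len(h))
        assert np.isclose(h.var(), cp.variance, rtol=0.05)

    def test_covariance_split_between_and_within_sublines(self, rng):
        lam, dfe = 25.0, NormalDFE(mean=0.004, sd=0.015)
        comp = simulate_h_components(20_000, lam, dfe, rng)
        q = lam * (0.004 ** 2 + 0.015 ** 2)
        cov_between = np.cov(comp["a1"], comp["b1"])[0, 1]
        cov_within = np.cov(comp["a1"], comp["a2"])[0, 1]
        assert np.isclose(cov_between, 1.5 * q, rtol=0.08)
        assert np.isclose(cov_within, 1.75 * q, rtol=0.08)

    def test_simulate_line_requires_dfe(self, rng):
        cfg = default_config()
        bare = FounderSpec("x", 2.5, n_ems_lines=1, noise_sd=0.2)
        with pytest.raises(ValueError, match="DFE"):
            simulate_line(bare, cfg, rng)
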