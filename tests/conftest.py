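import numpy as np
import pytest

from emsdfe import (
    FounderSpec,
    NormalDFE,
    SimulationConfig,
    default_config,
    simulate_experiment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_config():
    """A miniature two-founder experiment: one mutagenized, one control-only."""
    founders = (
        FounderSpec("alpha", 2.8, n_ems_lines=4, n_control_plants=40,
                    noise_sd=0.2, dfe=NormalDFE(mean=0.003, sd=0.012)),
        FounderSpec("beta", 2.3, n_ems_lines=0, n_control_plants=40,
                    noise_sd=0.3),
    )
    return SimulationConfig(founders=founders, n_per_subline=10, n_blocks=4,
                            seed=7)


@pytest.fixture(scope="session")
def small_table(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def study_table():
    """One realization of the full study design (5,040 plants)."""
    return simulate_experiment(default_config(seed=5))
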