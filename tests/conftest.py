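import numpy as np
import pytest

from driftccs import InstrumentConfig, SimulationScenario


@pytest.fixture(scope="session")
def instrument() -> InstrumentConfig:
    return InstrumentConfig()


@pytest.fixture(scope="session")
def noiseless_scenario() -> SimulationScenario:
    """Inverse-crime scenario: every stage should recover truth exactly."""
    return SimulationScenario(noise_sd=0.0, cal_cv=0.0, baseline=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_scenario() -> SimulationScenario:
    return SimulationScenario(seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
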