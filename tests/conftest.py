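import numpy as np
import pytest

from smrfes.synthetic import SimulationParams, generate_session


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture(scope="session")
def quiet_params() -> SimulationParams:
    """Artifact-free parameters for spectral oracles."""
    return SimulationParams(blink_rate=0.0, fes_artifact_amplitude=0.0)


@pytest.fixture(scope="session")
def small_session(default_params):
    return generate_session(8, default_params, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
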