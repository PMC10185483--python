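import numpy as np
import pytest

from thermogate import GatingParams, R, SimulationConfig, simulate_dataset


@pytest.fixture
def canonical_params():
    """The canonical steep heat-activated channel: dS = 125R, T_half = 40 C."""
    return GatingParams(delta_S=125.0 * R, T_half=313.15)


@pytest.fixture
def cold_params():
    """A TRPM8-like cold-activated channel: dS = -125R, T_half = 299 K."""
    return GatingParams(delta_S=-125.0 * R, T_half=299.0)


@pytest.fixture
def noisy_dataset(canonical_params):
    """25 temperatures spanning 298-328 K, 500 binomial trials each."""
    config = SimulationConfig(
        canonical_params, np.linspace(298.0, 328.0, 25), n_trials=500, seed=1
    )
    return simulate_dataset(config)


@pytest.fixture
def exact_dataset(canonical_params):
    """Noise-free proportions (n = 10^6 rounding) on a 15-point grid."""
    config = SimulationConfig(
        canonical_params, np.linspace(298.0, 328.0, 15), n_trials=10**6, noise="exact"
    )
    return simulate_dataset(config)
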