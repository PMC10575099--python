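import numpy as np
import pytest

from aquavital.synthetic import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def default_run():
    """One full-length simulated run at the default configuration."""
    cfg = SimulationConfig(seed=0)
    frames, stress, nutrients, truth = simulate_experiment(cfg)
    return cfg, frames, stress, nutrients, truth


@pytest.fixture(scope="session")
def short_run():
    """A 6-hour run for cheap I/O and pipeline tests."""
    cfg = SimulationConfig(duration_hours=6.0, seed=7)
    frames, stress, nutrients, truth = simulate_experiment(cfg)
    return cfg, frames, stress, nutrients, truth


def magnitude_series(frames, freq):
    return np.array([fr.channels[freq].magnitude for fr in frames])
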