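import numpy as np
import pytest

from vhitkit import CohortConfig, TraceConfig, simulate_cohort, simulate_trace


@pytest.fixture
def rng():
    return np.random.default_rng(20230425)


@pytest.fixture
def noiseless_config():
    """Trace configuration with every stochastic nuisance switched off."""
    return TraceConfig(
        noise_sd=0.0,
        vor_latency=0.0,
        saccade_probability=0.0,
        true_gain_left=1.04,
        true_gain_right=1.04,
        seed=11,
    )


@pytest.fixture
def noiseless_trace(noiseless_config):
    return simulate_trace(noiseless_config)


@pytest.fixture
def noisy_trace():
    return simulate_trace(TraceConfig(seed=42))


@pytest.fixture
def default_cohort():
    """17-participant cohort with the default subgroup structure."""
    return simulate_cohort(CohortConfig(seed=99))
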