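import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from m6akit import SimulationConfig, generate_truth, simulate_expression, simulate_merip_windows

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_transcripts=60, n_patients=3, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """A compact simulated cohort shared across read-only tests."""
    transcripts, truth = generate_truth(small_config)
    windows = simulate_merip_windows(truth, transcripts, small_config)
    expression = simulate_expression(truth, small_config)
    return {
        "config": small_config,
        "transcripts": transcripts,
        "truth": truth,
        "windows": windows,
        "expression": expression,
    }
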