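import numpy as np
import pytest

from thighgait import DetectionConfig, SimulationSpec, simulate


@pytest.fixture(scope="session")
def canonical_spec():
    return SimulationSpec(n_strides=20, stride_mean=1.2, stride_sd=0.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_sim(canonical_spec):
    """(recording, ground truth) for the canonical noiseless spec."""
    return simulate(canonical_spec)


@pytest.fixture
def config():
    return DetectionConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
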