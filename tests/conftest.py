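import numpy as np
import pytest

from striatal_gamma import TimeSeries
from striatal_gamma.fsi_network import (
    DriveSpec,
    NeuronParams,
    SynapseParams,
    build_topology,
    preprocess_drive,
    simulate,
)
from striatal_gamma.synthetic_data import synthetic_delta_drive


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def white_noise_ts(rng):
    """60 s of Gaussian white noise at 1 kHz."""
    return TimeSeries(rng.standard_normal(60_000), 1000.0)


@pytest.fixture(scope="session")
def small_topology():
    return build_topology(n_side=9, seed=0)


@pytest.fixture(scope="session")
def default_topology():
    return build_topology(n_side=15, seed=0)


@pytest.fixture(scope="session")
def default_drive():
    raw = synthetic_delta_drive(21.0, seed=0)
    d = preprocess_drive(raw, gain=1.25)
    return DriveSpec(d.samples[None, :], d.rate, gain=1.25)


@pytest.fixture(scope="session")
def default_sim(default_topology, default_drive):
    """One 20-s default-parameter network run shared across tests."""
    return simulate(
        default_topology,
        NeuronParams(),
        SynapseParams(),
        default_drive,
        dt=1e-4,
        duration=20.0,
        rho=1000.0,
        seed=0,
    )
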