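import numpy as np
import pytest

from batseg import SimConfig, compute_steps, generate_trip


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def sim_trip(sim_cfg):
    """One medium synthetic trip with ground truth (shared, read-only)."""
    return generate_trip(sim_cfg, seed=1, n_fix=600, trip_id="fix600")


@pytest.fixture(scope="session")
def sim_steps(sim_trip):
    trip, _ = sim_trip
    return compute_steps(trip)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
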