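import numpy as np
import pytest

from wristhr import simulate as sim
from wristhr.preprocess import process_session, window_session
from wristhr.session_io import PipelineConfig


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def short_schedule():
    return sim.make_schedule(
        [("A_rest", 1.5), ("B_read", 1.0), ("A_rest", 0.5), ("D_walk_slow", 1.0)]
    )


@pytest.fixture(scope="session")
def short_session(short_schedule):
    phys = sim.UserPhysiology(random_seed=42)
    return sim.simulate_session(short_schedule, phys, clock_offset=1.5)


@pytest.fixture(scope="session")
def short_processed(short_session, cfg):
    return process_session(short_session, cfg, hr_source="truth")


@pytest.fixture(scope="session")
def short_windows(short_processed, cfg):
    return window_session(short_processed, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
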