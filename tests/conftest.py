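import numpy as np
import pytest

from arlabels.events import infer_session_triplets
from arlabels.synth import NoiseSpec, default_demo_config, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo():
    """Default noiseless 60 s demo session plus ground truth."""
    return generate_session(default_demo_config())


@pytest.fixture(scope="session")
def demo_pipeline(demo):
    session, truth = demo
    records, kinematics, states, events = infer_session_triplets(session)
    return session, truth, records, kinematics, states, events


@pytest.fixture(scope="session")
def jitter_pipeline():
    """Demo with 1 mm translation jitter at a fixed seed."""
    cfg = default_demo_config(noise=NoiseSpec(jitter_sigma_t=1.0), seed=3)
    session, truth = generate_session(cfg)
    records, kinematics, states, events = infer_session_triplets(session)
    return session, truth, events


@pytest.fixture(scope="session")
def small_session():
    """Short (10 s) noiseless demo for I/O-heavy tests."""
    return generate_session(default_demo_config(duration=10.0, seed=2))
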