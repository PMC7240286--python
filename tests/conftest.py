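import numpy as np
import pytest

from metaproxy import task_sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A compact synthetic session shared across read-only tests."""
    return task_sim.simulate_session(
        n_subjects=6, trials_per_condition=30,
        rng=np.random.default_rng(777),
    )


@pytest.fixture(scope="session")
def default_session():
    """A full-size default session (23 subjects x 60 trials/condition)."""
    return task_sim.simulate_session(rng=np.random.default_rng(2024))
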