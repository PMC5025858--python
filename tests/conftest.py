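import numpy as np
import pytest

from obslearn import synth
from obslearn.task import TaskConfig, generate_session


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def session(task_config):
    return generate_session(task_config, seed=12345)


@pytest.fixture(scope="session")
def sim(session):
    """Session rewritten with softmax self behaviour + aligned learner output."""
    return synth.simulate_behaviour(session, synth.BehaviourParams(), seed=54321)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
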