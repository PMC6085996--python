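import numpy as np
import pytest

from twostep import AgentParams, TaskConfig, simulate_session
from twostep.synth import PRESETS


@pytest.fixture(scope="session")
def task_cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def short_cfg():
    return TaskConfig(n_laps=20)


@pytest.fixture(scope="session")
def small_sessions(short_cfg):
    """Four short hybrid-agent sessions (richest choice structure)."""
    rng = np.random.default_rng(123)
    return [
        simulate_session(PRESETS["hybrid"], "hybrid", short_cfg, rng) for _ in range(4)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
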