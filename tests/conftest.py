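import numpy as np
import pytest

from habitiron.agents import AgentParams, make_policy
from habitiron.task import TaskConfig, simulate_session


@pytest.fixture(scope="session")
def task_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def hybrid_session(task_config):
    """One complete 200-trial session from a mid-range hybrid agent."""
    rng = np.random.default_rng(12345)
    params = AgentParams(alpha1=0.5, alpha2=0.5, beta1=5.0, beta2=5.0,
                         lam=0.6, w=0.5, pi_persev=0.3)
    records, walk = simulate_session(make_policy(params, rng=rng), task_config, rng)
    return params, records, walk


def simulate_cohort_sessions(params_fn, n_sessions, seed, config=None):
    """Sessions of (meta, records) for cohort-level behavioral tests."""
    config = config or TaskConfig()
    root = np.random.default_rng(seed)
    sessions = []
    for j in range(n_sessions):
        rng = np.random.default_rng(root.integers(2**31 - 1))
        params = params_fn(j, rng)
        records, _ = simulate_session(make_policy(params, rng=rng), config, rng)
        meta = {"subject": f"s{j:03d}", "visit": 1, "session": f"s{j:03d}_v1"}
        sessions.append((meta, records, params))
    return sessions
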