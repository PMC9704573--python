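import numpy as np
import pytest

from twostep.agent import AgentParams, simulate_condition
from twostep.cohort import CohortSpec, _log_from_sim, simulate_cohort
from twostep.task import TaskConfig


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def typical_params():
    return AgentParams(alpha=0.6, beta_mb=1.4, beta_mf=1.5, beta_2=1.6, rho=1.0)


@pytest.fixture(scope="session")
def sim_log(config, typical_params):
    """One simulated 150-trial condition with the recorded choice probabilities."""
    rng = np.random.default_rng(123)
    sim = simulate_condition(typical_params, config, rng, record_probs=True)
    return _log_from_sim(sim), sim


@pytest.fixture(scope="session")
def small_cohort(config):
    """8 HC + 8 ED subjects with default generating distributions."""
    spec = CohortSpec(n_per_group={"HC": 8, "ED": 8})
    return simulate_cohort(spec, config, np.random.default_rng(42))
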