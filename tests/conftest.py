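import numpy as np
import pytest

from twostep.agent import AgentParams, make_agent
from twostep.cohort import CohortSpec, generate_cohort
from twostep.fitting import fit_cohort
from twostep.task import TaskConfig, run_session

STRONG_PARAMS = AgentParams(beta1=5, beta2=5, alpha1=0.6, alpha2=0.6, lam=0.6, omega=0.5, pi=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_config():
    return TaskConfig()


@pytest.fixture
def sim_session(default_config):
    """One 201-trial session from a mixed-control agent, fixed seed."""
    rng = np.random.default_rng(7)
    return run_session(make_agent(STRONG_PARAMS), default_config, rng)


@pytest.fixture(scope="session")
def small_cohort():
    """6 subjects x 3 interventions x 80 trials; null effects, some missing."""
    spec = CohortSpec(n_subjects=6, seed=3)
    return generate_cohort(spec, TaskConfig(n_trials=80))


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    return fit_cohort(small_cohort.trials, n_restarts=2, seed=0)
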