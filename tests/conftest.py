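import numpy as np
import pytest

from surpriserl.fitting import default_priors
from surpriserl.models import ModelParams
from surpriserl.simulate import simulate_agent
from surpriserl.tasks import build_bernoulli_bandit, build_risk_task


@pytest.fixture(scope="session")
def priors():
    return default_priors()


@pytest.fixture(scope="session")
def risk_task_cents():
    return build_risk_task(seed=0)


@pytest.fixture(scope="session")
def risk_task_scaled():
    # risky-task outcomes in units of 20 cents (0/1/2)
    return build_risk_task(seed=0, reward_scale=0.05)


@pytest.fixture(scope="session")
def bandit_task():
    return build_bernoulli_bandit((0.8, 0.2), (1.0, 1.0), 200)


@pytest.fixture(scope="session")
def ql_bandit_session(bandit_task):
    params = ModelParams("qlearning", alpha=0.4, beta=2.0)
    return simulate_agent(params, bandit_task, seed=11, subject_id="ql")


@pytest.fixture(scope="session")
def surprise_risk_session(risk_task_scaled):
    params = ModelParams("surprise", alpha=0.5, beta=2.0, d=0.4)
    return simulate_agent(params, risk_task_scaled, seed=5, subject_id="sp")
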