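import numpy as np
import pytest

from rewprop import AgentParams, TaskConfig, simulate_session


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def default_session(default_config):
    """One simulated session from the fitted-mean agent."""
    return simulate_session(AgentParams(), default_config, seed=1)


@pytest.fixture(scope="session")
def zero_learning_session(default_config):
    """Random responder: both learning rates zero, all choices coin flips."""
    params = AgentParams(alpha_gain=0.0, alpha_loss=0.0)
    return simulate_session(params, default_config, seed=2)
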