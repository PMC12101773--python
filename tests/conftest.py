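import numpy as np
import pytest

import goalmomentum as gm


@pytest.fixture(scope="session")
def exp1_config():
    return gm.make_experiment_config("exp1", seed=123)


@pytest.fixture(scope="session")
def momentum_params():
    return gm.ModelParams("momentum", alpha=0.4, gamma=0.95, switch_cost=0.5,
                          beta_goal=5.0, beta_action=5.0, alpha_ck=0.2)


@pytest.fixture(scope="session")
def momentum_dataset(exp1_config, momentum_params):
    return gm.simulate_participant(exp1_config, momentum_params, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
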