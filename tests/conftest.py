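import numpy as np
import pytest

import mabc


@pytest.fixture(scope="session")
def default_config():
    return mabc.TaskConfig()


@pytest.fixture(scope="session")
def canonical_session(default_config):
    """One generative run of the full model with canonical parameters."""
    return mabc.simulate_subject(default_config, mabc.CANONICAL_PARAMS,
                                 "mabc_full", seed=42)


@pytest.fixture(scope="session")
def random_session(default_config):
    """A coin-flipping subject on the default task."""
    rng = np.random.default_rng(7)
    return mabc.run_session(default_config, mabc.RandomPolicy(rng), rng_seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
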