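import numpy as np
import pytest

from learnarb.fitting import FitConfig
from learnarb.recovery import default_param_sampler
from learnarb.task import TaskConfig, generate_session


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def random_session(config):
    """A default-design session played by a uniform-random chooser."""
    return generate_session(config, agent="random",
                            rng=np.random.default_rng(11), list_index=0)


@pytest.fixture(scope="session")
def dynarb_session(config):
    params = dict(alpha_exp=0.5, beta_exp=5.0, mu=0.02,
                  alpha_obs=0.7, beta_obs=5.0, delta=0.2)
    return generate_session(config, agent=("dynarb", params),
                            rng=np.random.default_rng(12), list_index=1)


@pytest.fixture(scope="session")
def quick_fit():
    """Reduced-restart optimizer settings for unit tests."""
    return FitConfig(n_restarts=3)


@pytest.fixture()
def sampler():
    return default_param_sampler
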