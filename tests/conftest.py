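import warnings

import numpy as np
import pytest

# the arviz refactor notice and numba first-call compilation chatter are noise
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_logistic_study():
    """A small four-group study from the logistic generative model."""
    from fairddm import synthetic_data as sd

    return sd.simulate_study(n_per_group=4, model="logistic", seed=17)


@pytest.fixture(scope="session")
def small_ddm_study():
    """A small four-group study with diffusion-generated choices and RTs."""
    from fairddm import synthetic_data as sd

    return sd.simulate_study(n_per_group=4, model="ddm", seed=9)
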