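import numpy as np
import pytest

import podhess as ph

THETA_OU = np.array([0.46, 0.38])
THETA_MVOU = np.array([0.48, 0.78, 0.37, 0.32])
THETA_FHN = np.array([0.89, 0.98, 0.5, 0.79])


@pytest.fixture(scope="session")
def ou_model():
    return ph.univariate_ou()


@pytest.fixture(scope="session")
def mvou_model():
    return ph.bivariate_ou()


@pytest.fixture(scope="session")
def fhn_model():
    return ph.fitzhugh_nagumo()


@pytest.fixture(scope="session")
def ou_obs3(ou_model):
    """Three observations from the univariate OU data-generating setup."""
    return ph.simulate_observations(ou_model, THETA_OU, n=3, sim_level=6, seed=42)


@pytest.fixture(scope="session")
def ou_obs2(ou_model):
    return ph.simulate_observations(ou_model, THETA_OU, n=2, sim_level=6, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
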