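import numpy as np
import pytest

from fetalqc import SimParams, make_fixture_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_fixture_subject():
    """One severe-motion synthetic subject shared across tests."""
    return make_fixture_subject(seed=4)


@pytest.fixture(scope="session")
def small_params():
    """Fast simulation parameters: 96 volumes, modest latent rate (d=6)."""
    return SimParams(nu_g=2.0, nu_o=1.0 / 3.0, n_obs=96, seed=7)
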