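import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import popjoint as pj

settings.register_profile(
    "ci", max_examples=25, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_design():
    """2 sites / 1 transect / 2 sessions / 2 years / 1 observer."""
    return pj.generate_design(n_sites=2, n_transects=1, n_sessions=2,
                              n_years=2, nbox_fraction=0.5, n_observers=1,
                              seed=5)


@pytest.fixture(scope="session")
def tiny_cov(tiny_design):
    return pj.generate_covariates(tiny_design, seed=6)


@pytest.fixture(scope="session")
def tiny_params(tiny_design):
    p = pj.default_params(tiny_design, seed=7)
    p.a4[:] = 0.1
    p.d2[:] = -0.2
    return p


@pytest.fixture(scope="session")
def small_world():
    """30 sites / 5 transects / 3 sessions / 4 years, with banding."""
    design = pj.generate_design(n_sites=30, n_transects=5, n_sessions=3,
                                n_years=4, nbox_fraction=0.5, n_observers=3,
                                seed=11)
    cov = pj.generate_covariates(design, seed=12)
    params = pj.default_params(design, seed=13)
    ds = pj.simulate_dataset(design, cov, params, marking_rule=0.3, seed=14)
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
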