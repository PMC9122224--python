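import numpy as np
import pytest

import phagesieve as pg
from phagesieve.engine import scaled_census


@pytest.fixture(scope="session")
def resident():
    """Default resident strain (alpha=3e-6, beta=100, tau=15)."""
    return pg.DEFAULT_RESIDENT


@pytest.fixture(scope="session")
def env():
    """Default environment (B0=1000, delta=0.1)."""
    return pg.DEFAULT_ENV


@pytest.fixture(scope="session")
def small_setup():
    """Reduced-census (B0=100) strain/env/steady-state per strategy, cached.

    alpha is rescaled so alpha*B0 is unchanged; the per-host dynamics are
    those of the full-size system.
    """
    cache = {}

    def get(strategy):
        if strategy not in cache:
            res, env_s = scaled_census(
                pg.DEFAULT_RESIDENT.with_(strategy=strategy),
                pg.DEFAULT_ENV, 0.1)
            ss = pg.run_to_steady_state(res, env_s, seed=41)
            cache[strategy] = (res, env_s, ss)
        return cache[strategy]

    return get


@pytest.fixture(scope="session")
def default_steady():
    """Full-size (B0=1000) steady state per strategy, cached."""
    cache = {}

    def get(strategy):
        if strategy not in cache:
            res = pg.DEFAULT_RESIDENT.with_(strategy=strategy)
            cache[strategy] = (res, pg.run_to_steady_state(
                res, pg.DEFAULT_ENV, seed=17))
        return cache[strategy]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
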