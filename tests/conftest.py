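import numpy as np
import pytest

import whiskpop as wp


@pytest.fixture(scope="session")
def small_session() -> wp.SessionBundle:
    """A compact session with rate bins and behaviour markers."""
    cfg = wp.GeneratorConfig(n_neurons=60, n_trials=200, seed=11)
    return wp.generate_session(cfg)


@pytest.fixture(scope="session")
def default_session() -> wp.SessionBundle:
    """A default-sized session (epoch rates only)."""
    cfg = wp.GeneratorConfig(n_neurons=300, n_trials=500,
                             include_rate_bins=False, include_markers=False,
                             seed=3)
    return wp.generate_session(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
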