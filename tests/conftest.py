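import numpy as np
import pytest

from stimnet.pipeline import RunConfig
from stimnet.synth import synth_session


@pytest.fixture(scope="session")
def small_session():
    """One fixed synthetic null session shared by read-only tests."""
    return synth_session(n_channels=6, n_trials=10, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_config():
    return RunConfig(n_channels=6, n_trials=10)
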