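import numpy as np
import pytest

from burstnet import default_network_config


@pytest.fixture(scope="session")
def small_config():
    """A short representative network run (2 s) for simulator tests."""
    return default_network_config(
        i_ext=22.0, duration=2000.0, seed_topology=11, seed_init=12
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
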