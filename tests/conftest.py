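import numpy as np
import pytest

from tonopipe.synthetic import get_preset, standard_protocol


@pytest.fixture(scope="session")
def protocol():
    """The standard 330-tone protocol (11 freqs x 6 levels x 5 repeats)."""
    return standard_protocol(seed=0)


@pytest.fixture(scope="session")
def tr_preset():
    return get_preset("TR")


@pytest.fixture(scope="session")
def ct_preset():
    return get_preset("CT")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
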