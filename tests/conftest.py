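import numpy as np
import pytest

from mpmkit.phantom import default_protocol, make_layered_phantom, simulate_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def clean_phantom():
    """24^3 noiseless phantom without bias fields."""
    return make_layered_phantom(24, seed=11, ft_range=0.0, fr_range=0.0, fr_contrast_dev=0.0)


@pytest.fixture(scope="session")
def clean_series(clean_phantom, protocol):
    return simulate_protocol(clean_phantom, protocol)


@pytest.fixture(scope="session")
def biased_phantom():
    """24^3 noiseless phantom with +-20% transmit and per-contrast receive fields."""
    return make_layered_phantom(24, seed=12, ft_range=0.2, fr_range=0.15, fr_contrast_dev=0.05)


@pytest.fixture(scope="session")
def biased_series(biased_phantom, protocol):
    return simulate_protocol(biased_phantom, protocol)
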