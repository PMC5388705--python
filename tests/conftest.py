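import numpy as np
import pytest

from perfuscan import SpoiledGRESequence, load_registry


@pytest.fixture(scope="session")
def registry():
    """Packaged coefficient registry (as-printed convention)."""
    return load_registry()


@pytest.fixture(scope="session")
def registry_physical():
    return load_registry(convention="physical")


@pytest.fixture(scope="session")
def default_seq():
    return SpoiledGRESequence()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160101)
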