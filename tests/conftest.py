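import numpy as np
import pytest

from fluoroplan import bundled_implant, make_scene


@pytest.fixture(scope="session")
def implant_pair():
    return bundled_implant()


@pytest.fixture(scope="session")
def marker(implant_pair):
    return implant_pair[0]


@pytest.fixture(scope="session")
def implant(implant_pair):
    return implant_pair[1]


@pytest.fixture(scope="session")
def scene():
    """One default 30-degree scene used across read-only tests."""
    return make_scene(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
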