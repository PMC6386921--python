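import numpy as np
import pytest

from hierfusion.hierarchy import load_fixture
from hierfusion.synthetic import generate_dataset, preset


@pytest.fixture(scope="session")
def ebutton():
    return load_fixture("eButton")


@pytest.fixture(scope="session")
def ebutton_spec():
    return preset("ebutton-like", seed=3)


@pytest.fixture(scope="session")
def ebutton_data(ebutton_spec):
    """1500 aligned low-frame-rate samples from the chest-logger-like preset."""
    return generate_dataset(ebutton_spec, 1500, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
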