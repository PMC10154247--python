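import numpy as np
import pytest

from comamflux.network import load_kf1_model
from comamflux.synth import generate_kf1_default_scenario


@pytest.fixture(scope="session")
def kf1_model():
    return load_kf1_model()


@pytest.fixture(scope="session")
def kf1_scenario():
    return generate_kf1_default_scenario(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230206)
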