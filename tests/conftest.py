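import numpy as np
import pytest

from neoprey.io import generate_fixture, panel_to_neoantigens
from neoprey.params import TeslaFeatureParams, get_preset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def feature_params():
    return TeslaFeatureParams()


@pytest.fixture(scope="session")
def bbn_panel():
    return panel_to_neoantigens(generate_fixture("bbn963", seed=0))


@pytest.fixture
def human_preset():
    return get_preset("human_nsclc")


@pytest.fixture
def mouse_preset():
    return get_preset("mouse_c57bl6")
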