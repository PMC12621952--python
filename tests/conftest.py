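import numpy as np
import pytest

from nadesign.featurize import build_graph
from nadesign.model import ModelConfig, NAMPNN
from nadesign.synthetic import HelixSpec, make_duplex


@pytest.fixture(scope="session")
def duplex10():
    return make_duplex(HelixSpec(sequence="ACGTACGTAC"))


@pytest.fixture(scope="session")
def duplex10_graph(duplex10):
    return build_graph(duplex10)


@pytest.fixture(scope="session")
def small_model():
    cfg = ModelConfig(hidden_dim=32, n_encoder_layers=1, n_decoder_layers=1,
                      dropout=0.0, seed=7)
    return NAMPNN(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
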