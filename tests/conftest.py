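import numpy as np
import pytest

from moeyield.model import ModelConfig
from moeyield.synthetic import make_fixture


@pytest.fixture(scope="session")
def fixture_dataset():
    """Tiny deterministic dataset: 8 counties x 5 years."""
    return make_fixture(0)


@pytest.fixture(scope="session")
def small_config():
    """Model profile small enough for desk-scale training in tests."""
    return ModelConfig(d=8, n_enc_layers=1, n_heads=2, lstm_layers=1,
                       fusion_dims=(16, 8))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
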