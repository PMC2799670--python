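import numpy as np
import pytest
from hypothesis import settings

from crowdsim.config import ModelConfig, rng_stream
from crowdsim.psychophysics import get_bank

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def bank(config):
    return get_bank(config.encoder)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_rng(label: str) -> np.random.Generator:
    """Deterministic per-test stream, independent across labels."""
    return rng_stream(2024, label)
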