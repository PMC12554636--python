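import numpy as np
import pytest

from dreamgnn.config import DreamConfig
from dreamgnn.synthetic_fixtures import SyntheticSpec, generate, toy_worked_example


@pytest.fixture(scope="session")
def toy():
    return toy_worked_example()


@pytest.fixture(scope="session")
def small_bundle():
    """Default desk-scale synthetic dataset (60 drugs x 40 diseases)."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def tiny_bundle():
    """Very small dataset for fast training-path tests."""
    return generate(SyntheticSpec(n_drugs=24, n_diseases=16, embed_dim=16, seed=3))


@pytest.fixture(scope="session")
def fast_config():
    """Few-epoch configuration: exercises every code path quickly."""
    return DreamConfig.small(epochs=30, patience=30)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
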