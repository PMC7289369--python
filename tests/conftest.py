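import numpy as np
import pytest

from evomi.features import MRAConfig
from evomi.simulate import generate_feature_patterns, make_benchmark_suite


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_mra_config():
    return MRAConfig()


@pytest.fixture(scope="session")
def small_patterns():
    """30-feature, 3-class matrix with 10 informative columns."""
    matrix, informative = generate_feature_patterns(
        n_patterns=90, n_features=30, n_informative=10, effect_size=1.5, seed=7
    )
    return matrix, informative


@pytest.fixture(scope="session")
def benchmark_suite():
    return make_benchmark_suite(seed=1)
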