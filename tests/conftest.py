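import numpy as np
import pytest

from mmda.adapt import AdaptationConfig
from mmda.models import TrainConfig, train_source_suite
from mmda.synthetic import default_feature_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced feature-tier benchmark shared by the slower tests."""
    return default_feature_benchmark(seed=0, n_per_class=60)


@pytest.fixture(scope="session")
def small_bundles(small_benchmark):
    return train_source_suite(
        small_benchmark.sources, d=16, seed=0, cfg=TrainConfig(epochs=15)
    )


@pytest.fixture
def quick_adapt_cfg():
    return AdaptationConfig(epochs=8, warmup_epochs=2, seed=0)
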