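import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import dermfusion as df
from dermfusion.synthetic import SyntheticSpec

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def benchmark_spec(seed: int) -> SyntheticSpec:
    """The standard selection benchmark: 8 informative among 52 noise columns."""
    return SyntheticSpec(n_samples=200, n_classes=7, n_informative=8,
                         n_redundant=0, n_noise=52, class_separation=3.0,
                         seed=seed)


@pytest.fixture(scope="session")
def benchmark_data():
    """(FeatureMatrix, truth) for benchmark seed 0; shared across tests."""
    return df.make_features(benchmark_spec(0))
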