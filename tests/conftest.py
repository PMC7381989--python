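import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glycoplan import synth

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def meal_db():
    """A mid-sized synthetic meal database shared across tests."""
    return synth.gen_meal_db(60, seed=0)


@pytest.fixture(scope="session")
def small_clusters():
    """A quick, well-separated classification problem (5 classes, 40 each)."""
    return synth.gen_bottleneck_features(
        n_classes=5, n_per_class=40, n_features=8, separation=6.0, noise=1.0, seed=0
    )


@pytest.fixture(scope="session")
def qa_corpus():
    return synth.gen_qa_pairs(40, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
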