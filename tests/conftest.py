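import numpy as np
import pytest

from grainsight import synthetic


@pytest.fixture(scope="session")
def grain_samples():
    """Ten seeded grain images (two per class) with ground-truth masks."""
    return synthetic.gen_grain_images(n_per_class=2, n_classes=5, hw=128, seed=0)


@pytest.fixture(scope="session")
def feature_fixture():
    """Standard planted feature matrix: 10 informative, 20 redundant, 30 noise."""
    spec = synthetic.SyntheticFeatureSpec(seed=1)
    return synthetic.gen_feature_matrix(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
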