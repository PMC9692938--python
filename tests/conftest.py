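import numpy as np
import pytest

from antcad.synthetic import (
    SyntheticImageSpec,
    SyntheticTableSpec,
    make_feature_table,
    make_images,
)


@pytest.fixture(scope="session")
def planted():
    """Default planted table (300 x 60, 8 informative, 4 redundant, 3 classes)."""
    return make_feature_table(SyntheticTableSpec())


@pytest.fixture(scope="session")
def separable():
    """Strongly separated planted table (effect size 3, no redundancy)."""
    return make_feature_table(
        SyntheticTableSpec(n_samples=150, n_features=20, n_informative=5,
                           n_redundant=0, effect_size=3.0, seed=11)
    )


@pytest.fixture(scope="session")
def grating_images():
    """Three-class synthetic image set: gratings and a blob, light noise."""
    return make_images(SyntheticImageSpec(n_per_class=12, noise_sd=10.0, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
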