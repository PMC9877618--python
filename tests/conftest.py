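import numpy as np
import pytest

from sielunet import GeneratorSpec, generate_feature_table, generate_sequences
from sielunet.dataprep import fit_scaler


@pytest.fixture(scope="session")
def small_dataset():
    """40 sequences/class with the default planted signal."""
    return generate_sequences(GeneratorSpec(n_per_class=40, length_range=(60, 120), seed=7))


@pytest.fixture(scope="session")
def separable_table():
    """Strongly separated Gaussian feature table (d=3 on 5 columns)."""
    X, y, bayes = generate_feature_table(GeneratorSpec(n_per_class=100, effect_size=3.0, seed=5))
    scaler = fit_scaler(X)
    return scaler.transform(X), y, bayes


@pytest.fixture
def rng():
    return np.random.default_rng(0)
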