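import numpy as np
import pytest

from metabovote.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (30 x 80) shared across read-only tests."""
    return generate(SyntheticConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def scaled_random(rng, n=12, p=7):
    """UV-scaled random matrix helper used by several oracle tests."""
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    X /= X.std(axis=0, ddof=1)
    return X
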