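import numpy as np
import pytest

from imcpheno import default_human_signatures, human_rules


@pytest.fixture(scope="session")
def human_sig():
    return default_human_signatures()


@pytest.fixture(scope="session")
def human_ruleset():
    return human_rules()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_count_image(rng, max_side=32, p_zero=0.5, scale=20.0):
    """A random non-negative count-like image with plenty of exact zeros."""
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    img = rng.gamma(1.0, scale, size=(h, w))
    img[rng.random((h, w)) < p_zero] = 0.0
    return img
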