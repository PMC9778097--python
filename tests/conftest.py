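import numpy as np
import pytest

from countsimbench import make_fixture


@pytest.fixture(scope="session")
def tiny_counts():
    return make_fixture("tiny_counts")


@pytest.fixture(scope="session")
def null_nb():
    return make_fixture("null_nb", seed=3)


@pytest.fixture(scope="session")
def two_blob():
    return make_fixture("two_blob", seed=4)


@pytest.fixture(scope="session")
def ngsspg1_small():
    return make_fixture("ngsspg1_small", seed=2)


@pytest.fixture(scope="session")
def ngsspg2_small():
    return make_fixture("ngsspg2_small", seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
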