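import numpy as np
import pytest

from physiostate.synthetic import TableGenConfig, gen_feature_table, make_xor_table


@pytest.fixture(scope="session")
def xor_table():
    return make_xor_table()


@pytest.fixture(scope="session")
def planted_table():
    return gen_feature_table(TableGenConfig(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
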