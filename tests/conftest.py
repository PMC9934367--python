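import numpy as np
import pytest

from nachr_pharm import load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def core(table1):
    return table1.core_panel()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230517)
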