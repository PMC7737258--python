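import numpy as np
import pytest

from cupsim import load_table2_fixture


@pytest.fixture(scope="session")
def table2():
    """The packaged 13x9 published measurement grid."""
    return load_table2_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
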