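import numpy as np
import pytest

import tapspath as tp


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def mueller_brown():
    return tp.get_potential("mueller_brown")


@pytest.fixture(scope="session")
def staircase():
    from tests.helpers import wildtype_staircase

    system, spec = wildtype_staircase()
    return system, spec
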