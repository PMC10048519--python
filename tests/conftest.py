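import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: Printed temperature-resolved binding constants (K, L/mol) of the study.
TABLE3_PAIRS = [(297.0, 4.13e4), (304.0, 3.68e4), (311.0, 1.65e4)]


@pytest.fixture
def table3_pairs():
    return list(TABLE3_PAIRS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
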