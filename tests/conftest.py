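import numpy as np
import pytest

import snptrace as st


@pytest.fixture(scope="session")
def panel():
    return st.load_panel()


@pytest.fixture(scope="session")
def rs1410592(panel):
    return next(s for s in panel if s.rsid == "rs1410592")  # A/C


@pytest.fixture
def rng():
    return np.random.default_rng(20130927)
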