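import numpy as np
import pytest
from hypothesis import settings

import goldmap as gm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def window100():
    return gm.SpatialWindow.square(100.0)


@pytest.fixture
def sheet():
    """The 1 um^2 membrane-sheet window."""
    return gm.SpatialWindow.square(1000.0)


@pytest.fixture
def csr170(sheet):
    return gm.generate_csr(170, window=sheet, seed=11, image_id="csr170")


@pytest.fixture
def small_envelope(csr170):
    """A quick 99% CSR envelope matched to the csr170 pattern."""
    return gm.csr_envelope(csr170, n_sim=120, seed=7)
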