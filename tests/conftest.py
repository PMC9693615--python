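import numpy as np
import pytest

from cobedose import DosingDomain, KernelSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def grid_1d():
    """Fine single-administration grid (101 doses)."""
    return DosingDomain.regular_grid(101, 1)


@pytest.fixture
def coarse_1d():
    """Coarse single-administration grid (6 doses)."""
    return DosingDomain.regular_grid(6, 1)


@pytest.fixture
def kernel_1d():
    return KernelSpec((0.2,))
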