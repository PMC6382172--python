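import numpy as np
import pytest

from dendrophase import CableParams, TriangularPRC


@pytest.fixture
def linear_cable() -> CableParams:
    """Passive cable with the reference parameters used throughout: tau=10 ms,
    band from the soma out to 0.44 characteristic lengths."""
    return CableParams(tau=10.0, lam=1.0, r_outer=0.44)


@pytest.fixture
def unit_triangle() -> TriangularPRC:
    return TriangularPRC(theta=0.8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
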