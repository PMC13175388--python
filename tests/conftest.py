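import numpy as np
import pytest

from fpboundary import build_penalty, build_spline_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def cubic_spec():
    """The default estimation basis: cubic, K=8 on [0, 1]."""
    return build_spline_spec(0.0, 1.0, 8, 4)


@pytest.fixture
def integral_penalty(cubic_spec):
    return build_penalty(cubic_spec, "second_derivative_integral")
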