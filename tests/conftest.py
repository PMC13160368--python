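import numpy as np
import pytest

from fdconformal import (
    FunctionalSample,
    Warping,
    uniform_grid,
)
from fdconformal.simulate import two_peak_values


@pytest.fixture
def grid101():
    return uniform_grid(101)


@pytest.fixture
def two_peak(grid101):
    """A fixed two-bump function (coefficients 2, 2)."""
    return FunctionalSample(grid101, two_peak_values(grid101, 2.0, 2.0))


@pytest.fixture
def beta21_warp(grid101):
    """Beta(2,1) CDF, i.e. gamma(t) = t^2."""
    return Warping(grid101, grid101**2)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
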