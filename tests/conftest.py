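import numpy as np
import pytest

from lockin.curves import InfluenceCurve


class IdentityCurve(InfluenceCurve):
    """f(x) = x: the classical Polya urn, whose limit share is Uniform(0, 1)
    when started from one ball of each colour."""

    def _value(self, x):
        return x

    def left_limit(self, eps=1e-4):
        return 0.5

    def right_limit(self, eps=1e-4):
        return 0.5


@pytest.fixture
def identity_curve():
    return IdentityCurve()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
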