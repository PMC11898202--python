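import numpy as np
import pytest

from pigtherm.geometry import EarSide, OrientedBox, box_from_center


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def random_box(rng, center_lo=30.0, center_hi=220.0, length=(15.0, 45.0),
               width=(4.0, 12.0), label=None):
    """A random oriented rectangle for property tests."""
    c = rng.uniform(center_lo, center_hi, size=2)
    return box_from_center(c, rng.uniform(*length), rng.uniform(*width),
                           rng.uniform(0.0, 360.0), label)


def unit_square(label=None):
    return OrientedBox(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]), label)
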