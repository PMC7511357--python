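import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def disk_mask(shape, cy, cx, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


@pytest.fixture
def make_disk():
    return disk_mask
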