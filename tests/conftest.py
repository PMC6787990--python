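import numpy as np
import pytest

from exocnv.hmm import HMMParameters
from exocnv.intervals import TargetInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def params():
    return HMMParameters()


@pytest.fixture
def uniform_targets():
    """Ten adjacent 100 bp targets on one chromosome, 100 bp gaps."""
    return [TargetInterval("1", 1 + i * 200, 100 + i * 200) for i in range(10)]


def make_matrix(rng, s=12, t=40, loc=100.0, scale=5.0):
    from exocnv.matrix import ReadDepthMatrix

    targets = [TargetInterval("1", 1 + j * 500, 200 + j * 500) for j in range(t)]
    depths = np.clip(rng.normal(loc, scale, size=(s, t)), 0.0, None)
    return ReadDepthMatrix(
        samples=[f"S{i:02d}" for i in range(s)], targets=targets, depths=depths
    )


@pytest.fixture
def small_matrix(rng):
    return make_matrix(rng)
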