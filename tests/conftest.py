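import numpy as np
import pytest

from ibrcluster.partitions import SizeSpec
from ibrcluster.gaussian import GaussianRLPPSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def spec_1d():
    """Symmetric 1-d NIW model, two equal clusters of two points."""
    return GaussianRLPPSpec.symmetric(1, SizeSpec.fixed((2, 2)), kappa=3.0)


@pytest.fixture
def well_separated_1d():
    """Four 1-d points with an unambiguous 2+2 split."""
    return np.array([[0.1], [0.2], [5.0], [5.1]])
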