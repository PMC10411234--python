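import numpy as np
import pytest

from obseval import Gaussian


@pytest.fixture
def std_gauss_2d():
    """Standard 2D normal."""
    return Gaussian(mean=[0.0, 0.0], cov=np.eye(2))


@pytest.fixture
def shifted_gauss_2d():
    """2D normal shifted by 2 along the first pixel; D_B = 0.5 vs standard."""
    return Gaussian(mean=[2.0, 0.0], cov=np.eye(2))
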