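import numpy as np
import pytest

from quantgen_arch import ModelParams


@pytest.fixture
def human_like_params():
    """Parameters in the range used for the height/BMI-style analyses:
    moderate pleiotropy, N = 10^4, human per-site mutation rate, ~Mb-scale
    target."""
    return ModelParams(n=10, w=1.0, N=10_000, u=1.25e-8, L=1_000_000)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
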