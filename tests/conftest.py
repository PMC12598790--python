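import numpy as np
import pytest

from dnabind.synthetic import INTERCALATOR_TRUTH, PAPER_TRUTH


@pytest.fixture
def truth():
    """Noiseless study conditions (printed estimates as ground truth)."""
    return PAPER_TRUTH.noiseless()


@pytest.fixture
def noisy_truth():
    """Study conditions with the default (realistic) noise levels."""
    return PAPER_TRUTH


@pytest.fixture
def intercalator_truth():
    return INTERCALATOR_TRUTH.noiseless()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
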