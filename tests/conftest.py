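import numpy as np
import pytest

from ptbquant.smtirf import StepCountHistogram

#: canonical seed for every derandomised stochastic test
SEED = 0


@pytest.fixture
def exact_hist() -> StepCountHistogram:
    """Counts exactly proportional to the truncated binomial at n=4, theta=0.5.

    pmf = (4/15, 6/15, 4/15, 1/15); N = 1500 gives integer counts
    (400, 600, 400, 100).
    """
    return StepCountHistogram({1: 400, 2: 600, 3: 400, 4: 100})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)
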