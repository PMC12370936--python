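import numpy as np
import pytest

from relapath.dual_module import Hyperparams

# keep BLAS single-threaded assumptions honest on shared machines
SMALL_SIDE = 56   # smallest side with a 2x2 final pool; ~16x cheaper than 224


@pytest.fixture(scope="session")
def hyper():
    return Hyperparams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
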