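import warnings

import numpy as np
import pytest

from scsift import circuit as cm
from scsift import stimuli as st

# fold redraws on sparse location labels are expected in small tests
warnings.filterwarnings("ignore", message="could not draw folds")


@pytest.fixture(scope="session")
def circuit_config() -> cm.CircuitConfig:
    """Default circuit (Table-1 kernels, 5x5 grid); rate normalization
    computed once per session."""
    cfg = cm.CircuitConfig()
    cfg.rate_scale  # warm the cache
    return cfg


@pytest.fixture(scope="session")
def standard_loom() -> st.StimulusMovie:
    return st.loom_movie((0.0, 0.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
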