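import numpy as np
import pytest

from mpmr import synth


@pytest.fixture(scope="session")
def gt_small():
    """Small heterogeneous ground-truth field shared across tests."""
    return synth.generate_ground_truth((16, 16), pixel_size=320.0, seed=7)


@pytest.fixture(scope="session")
def he_slide():
    """One HE slide with generator truth (a few seconds to render)."""
    return synth.generate_slide("HE", (1000, 1000), 2.0, seed=5)


@pytest.fixture(scope="session")
def dce_time_grid():
    return np.arange(synth.DEFAULT_N_DYNAMICS, dtype=float) * synth.DEFAULT_DT
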