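import numpy as np
import pytest

import dynconn
from dynconn.windows import WindowParams, window_connectivity


@pytest.fixture(scope="session")
def gt():
    """Default two-state, two-group generating model (27 nodes)."""
    return dynconn.default_ground_truth(seed=11)


@pytest.fixture(scope="session")
def small_cohort(gt):
    """12-subject cohort (6 per group), full-length series."""
    series, subjects, paths = dynconn.simulate_cohort(
        gt, n_per_group=6, T=230, seed=21
    )
    return series, subjects, paths


@pytest.fixture(scope="session")
def small_wfc(small_cohort):
    series, _, _ = small_cohort
    return [window_connectivity(ts, WindowParams()) for ts in series]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
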