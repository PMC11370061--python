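import warnings

import numpy as np
import pandas as pd
import pytest

from motorstrat.preprocess import batch_correct, merge_and_filter
from motorstrat.synthetic import (
    KinematicSimConfig,
    ProfileSimConfig,
    simulate_profiles,
    simulate_reach_to_drop,
)

# umap/numba emit many benign warnings under repeated fitting
warnings.filterwarnings("ignore", module="umap")
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def profile_table() -> pd.DataFrame:
    """One simulated study cohort at the default conditions."""
    return simulate_profiles(ProfileSimConfig(seed=1))


@pytest.fixture(scope="session")
def corrected_autism(profile_table):
    corrected = batch_correct(merge_and_filter([profile_table]).table)
    return corrected.table[corrected.table["diagnosis"] == "autism"]


@pytest.fixture(scope="session")
def noiseless_trials():
    """Ten identical trials: zero trajectory noise, zero duration jitter."""
    cfg = KinematicSimConfig(seed=3, duration_jitter=0.0)
    return simulate_reach_to_drop(cfg, 0.0, "NOISELESS")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
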