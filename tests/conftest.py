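import dataclasses

import numpy as np
import pandas as pd
import pytest

from adaptkit.fnirs import default_montage
from adaptkit.synthetic import (
    CohortConfig,
    FnirsNoiseConfig,
    default_block_design,
    simulate_fnirs_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_montage():
    """8 long + 2 short channels, 4-per-ROI assignment over the first ROIs."""
    return default_montage(n_long=8, n_short=2, channels_per_roi=4)


@pytest.fixture
def block_design():
    return default_block_design()


@pytest.fixture
def noiseless_recording(small_montage, block_design):
    beta_map = {c: {"EarlyAdapt": 0.1}
                for c in small_montage.loc[~small_montage.is_short, "channel"]}
    return simulate_fnirs_recording(block_design, beta_map,
                                    FnirsNoiseConfig.off(), seed=0,
                                    channels=small_montage)


@pytest.fixture
def tiny_cohort_config():
    """Small, fast cohort used by unit tests (not the acceptance cohort)."""
    return dataclasses.replace(CohortConfig(seed=5), n_pwms=4, n_hc=4,
                               n_strides=120, n_baseline=60,
                               include_deadaptation=False)


def make_sim_config(seed, n_strides=500, deadapt=False, zero=False):
    cfg = dataclasses.replace(CohortConfig(seed=seed), n_strides=n_strides,
                              include_deadaptation=deadapt)
    return cfg.zeroed() if zero else cfg
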