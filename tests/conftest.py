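import numpy as np
import pytest

from weanwave.preprocess import PreprocessConfig
from weanwave.sbt_sim import SimConfig, default_priors, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six 60-second patients, three failures; small enough for fast tests."""
    cfg = SimConfig(n_patients=6, failure_prevalence=0.5, duration_s=60.0,
                    cough_rate_per_min=0.0, seed=7)
    return simulate_cohort(default_priors(), cfg)


@pytest.fixture(scope="session")
def tiny_record(tiny_cohort):
    return tiny_cohort[0]


@pytest.fixture(scope="session")
def pp_tiny():
    """Crop/fold settings matched to 60-second recordings."""
    return PreprocessConfig(crop_len_waveform=1300, crop_len_numeric=70,
                            fold_width_waveform=130, fold_width_numeric=70)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
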