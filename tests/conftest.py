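import numpy as np
import pytest

from ratsleep import pipeline
from ratsleep import synthetic_data as sd

#: short quantitative-EEG windows used throughout the tests (ZT seconds):
#: 30 min inside the inactive phase and 30 min inside the active phase
TEST_WINDOWS = ((7 * 3600.0, 7 * 3600.0 + 1800.0),
                (19 * 3600.0, 19 * 3600.0 + 1800.0))


@pytest.fixture(scope="session")
def small_cohort():
    """7 control + 8 disease-like animals, 24 h hypnograms, windowed EEG."""
    cfg = sd.SimulationConfig(duration=86400, seed=2024, eeg_windows=TEST_WINDOWS)
    return sd.simulate_cohort(cfg, sd.control_profile(), sd.ad_like_profile())


@pytest.fixture(scope="session")
def small_study_config():
    return pipeline.StudyConfig(windows=TEST_WINDOWS, n_boot=2000, seed=7)


@pytest.fixture(scope="session")
def small_results(small_cohort, small_study_config):
    cohort = pipeline.from_simulated(small_cohort)
    return pipeline.run_all(cohort, small_study_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
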