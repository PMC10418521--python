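import numpy as np
import pytest

from fcleak.synthetic import SynthConfig, generate_cohort, generate_fc_cohort
from fcleak.types import vectors_to_frame


@pytest.fixture(scope="session")
def default_config():
    """The study's default cohort: 50 subjects x 2 scans, P=30, T=200,
    alpha=1.0, beta=0.5, sigma=0.5, rank 3, TR 2 s."""
    return SynthConfig()


@pytest.fixture(scope="session")
def default_fc_cohort(default_config):
    """Fast-path FC vectors + cohort table for the default config."""
    vectors, cohort = generate_fc_cohort(default_config)
    return vectors, cohort


@pytest.fixture(scope="session")
def default_fc_table(default_fc_cohort):
    vectors, cohort = default_fc_cohort
    return vectors_to_frame(vectors), cohort


@pytest.fixture(scope="session")
def small_fc_table():
    """A small cohort for fast model-fitting tests."""
    cfg = SynthConfig(n_subjects=20, n_rois=10, seed=5)
    vectors, cohort = generate_fc_cohort(cfg)
    return vectors_to_frame(vectors), cohort


@pytest.fixture(scope="session")
def tiny_ts_cohort():
    """Small timeseries cohort (12 subjects x 2 scans, P=10, T=120)."""
    cfg = SynthConfig(n_subjects=12, n_rois=10, n_timepoints=120, seed=3)
    scans, cohort = generate_cohort(cfg)
    return scans, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
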