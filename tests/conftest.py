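import numpy as np
import pytest

import peersusc as ps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_cohort():
    """Canonical simulation conditions: n=200, betas (0.4, 0.1, 0.3), noise 0.5.

    Records-only (no timeseries draw) — the moderator is the generated
    ground-truth connectivity, which is what the outcome model uses.
    """
    cfg = ps.SynthConfig(n_subjects=200, noise_sd=0.5, cov_betas={}, seed=20)
    return ps.generate_cohort(cfg, with_timeseries=False)


@pytest.fixture(scope="session")
def study_fit(study_cohort):
    """Step-3 moderation fit of the canonical cohort (generated outcome scale)."""
    return ps.ModerationModel(study_cohort.records, outcome="behavior_composite").fit()


@pytest.fixture(scope="session")
def imaging_cohort():
    """Small cohort with full timeseries + confounds, for pipeline tests."""
    cfg = ps.SynthConfig(n_subjects=24, seed=77)
    return ps.generate_cohort(cfg)
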