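"""Shared fixtures: small deterministic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from speechtrack import ContinuousRecording, CohortSpec
from speechtrack.simulate import simulate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Desk-scale cohort: short trials, few channels, fast to simulate."""
    return CohortSpec(
        n_subjects=2, n_trials=6, trial_duration=20.0, n_channels=8, seed=42
    )


@pytest.fixture(scope="session")
def small_subject(small_cohort_spec):
    """One simulated subject of the small cohort (recordings, envelopes, truth)."""
    return simulate_subject(small_cohort_spec, 0)


@pytest.fixture
def random_recording(rng):
    return ContinuousRecording(rng.standard_normal((4, 2048)), fs=256.0)
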