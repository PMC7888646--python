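import numpy as np
import pytest

from stepspace import MultiSensorRecording, SimConfig, simulate_cohort
from stepspace.pipeline import process_recording


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed cohort with default (noisy) study conditions."""
    cfg = SimConfig(n_hv=6, n_pd=6, walk_duration_s=30.0, seed=1234)
    recordings, cohort, truths = simulate_cohort(cfg)
    return cfg, recordings, cohort, truths


@pytest.fixture(scope="session")
def small_sessions(small_cohort):
    _, recordings, cohort, _ = small_cohort
    sessions = {k: process_recording(rec) for k, rec in recordings.items()}
    return sessions, cohort


@pytest.fixture
def tiny_recording():
    """Two-site recording with deterministic content for IO round trips."""
    rng = np.random.default_rng(7)
    return MultiSensorRecording(
        participant_id="P01",
        session_id="s1",
        sample_rate=128.0,
        sites={
            "left_foot": rng.normal(size=(256, 3)),
            "right_foot": rng.normal(size=(256, 3)),
        },
    )
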