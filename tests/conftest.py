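"""Shared fixtures: small synthetic studies reused across test modules."""

import numpy as np
import pytest

from mirp.synth import (StudyConfig, default_montage, inject_artifacts,
                        make_cohort, simulate_run)

SEED = 7


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def default_cfg():
    return StudyConfig()


@pytest.fixture(scope="session")
def default_run(default_cfg):
    """One full-length run of the default paradigm (40 trials, 9 s each)."""
    profile = make_cohort(default_cfg, SEED)[0]
    return simulate_run(profile, default_cfg, session=1, run=1, seed=SEED)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Deterministic oscillation-only configuration for closed-form checks:
    fixed ERD depth 0.5, no background, no drift, no boosts."""
    return StudyConfig(
        noise_scale=0.0, erd_depth_range=(0.5, 0.5), coupling=1.0,
        session_drift_sd=0.0, erd_session_sd=0.0, erd_trial_sd=0.0,
        theta_boost=0.0, gamma_boost=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_runs(noiseless_cfg):
    profile = make_cohort(noiseless_cfg, 3)[0]
    profile.noise_scale = 0.0
    return [simulate_run(profile, noiseless_cfg, 1, r, seed=5) for r in (1, 2)]


@pytest.fixture(scope="session")
def artifact_cfg():
    """Short runs (12 trials) with busy artifact rates for EOG/EMG tests."""
    return StudyConfig(trials_per_run=12, blink_rate_per_min=12.0,
                       emg_rate_per_min=8.0)


@pytest.fixture(scope="session")
def artifact_pair(artifact_cfg):
    """(clean run, same run with blink/EMG artifacts and EOG channels)."""
    profile = make_cohort(artifact_cfg, 21)[0]
    clean = simulate_run(profile, artifact_cfg, 1, 1, seed=21)
    dirty = inject_artifacts(clean, profile)
    return clean, dirty, profile


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
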