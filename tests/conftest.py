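import numpy as np
import pytest

from armclone import (
    ArmModel,
    PhaseTiming,
    SubjectProfile,
    generate_target_grid,
    synthesize_subject,
)


@pytest.fixture(scope="session")
def arm():
    return ArmModel()


@pytest.fixture(scope="session")
def grid():
    return generate_target_grid()


@pytest.fixture(scope="session")
def timing():
    return PhaseTiming()


@pytest.fixture(scope="session")
def noiseless_profile():
    return SubjectProfile(
        "S0", swivel_deg=24.0, angle_noise_sd=0.0, timing_jitter_frac=0.0, seed=5
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_profile, arm, grid, timing):
    """4 repetitions x 8 targets, one session, no noise or jitter."""
    return synthesize_subject(
        noiseless_profile, arm, grid, timing, repetitions=4, sessions=1
    )


@pytest.fixture(scope="session")
def noisy_dataset(arm, grid, timing):
    """One default-style noisy subject, both sessions."""
    profile = SubjectProfile(
        "S1", swivel_deg=18.0, angle_noise_sd=2.0, timing_jitter_frac=0.10, seed=101
    )
    return synthesize_subject(profile, arm, grid, timing, repetitions=4, sessions=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
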