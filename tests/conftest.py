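"""Shared fixtures: synthetic walks reused across test modules."""

import numpy as np
import pytest

from zuptgait import (
    ArtifactSpec,
    GaitSpec,
    inject_artifacts,
    synth_walk_trajectory,
    trajectory_to_imu,
)


@pytest.fixture(scope="session")
def clean_walk():
    """Deterministic noiseless 10-stride straight walk (1.2 m, 1.0 s strides)."""
    spec = GaitSpec(
        n_strides=10, stride_length_mean=1.2, stride_length_sd=0.0,
        stride_time_mean=1.0, stride_time_sd=0.0, seed=1,
    )
    traj = synth_walk_trajectory(spec)
    rec = trajectory_to_imu(traj)
    return spec, traj, rec


@pytest.fixture(scope="session")
def variable_walk():
    """Noiseless walk with per-stride length/time variation."""
    spec = GaitSpec(n_strides=12, seed=4)
    traj = synth_walk_trajectory(spec)
    rec = trajectory_to_imu(traj)
    return spec, traj, rec


@pytest.fixture(scope="session")
def noisy_walk():
    """30-stride walk with default noise/bias artifacts."""
    spec = GaitSpec(n_strides=30, seed=3)
    traj = synth_walk_trajectory(spec)
    rec = inject_artifacts(trajectory_to_imu(traj), ArtifactSpec(seed=7))
    return spec, traj, rec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
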