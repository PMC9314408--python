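"""Shared fixtures: arena configurations and a small synthetic cohort.

The cohort fixture is session-scoped (generation is the expensive step) and
deliberately small — 3 animals per group, two 5-minute sessions — enough to
exercise every pipeline stage.
"""

import math

import numpy as np
import pytest

from carousel import ArenaConfig, CohortSpec, Segment, Trajectory
from carousel.pipeline import featurize_cohort, segment_cohort
from carousel.simulate import generate_cohort, truth_label


@pytest.fixture(scope="session")
def config():
    return ArenaConfig()


@pytest.fixture(scope="session")
def static_config():
    """Non-rotating arena: room and arena frames coincide, which makes
    hand-constructed kinematic oracles exact."""
    return ArenaConfig(rotation_rate=0.0, arena_phase0=0.0)


@pytest.fixture(scope="session")
def small_cohort(config):
    spec = CohortSpec(n_per_group=3, n_sessions=2, session_duration=300.0, seed=7)
    trajectories, truth = generate_cohort(spec, config)
    return spec, trajectories, truth


@pytest.fixture(scope="session")
def small_segments(small_cohort, config):
    _, trajectories, truth = small_cohort
    segments = segment_cohort(trajectories, config)
    labels = np.array([truth_label(truth, s) for s in segments])
    return segments, labels


@pytest.fixture(scope="session")
def small_features(small_segments, config):
    segments, labels = small_segments
    return featurize_cohort(segments, config), labels


def make_trajectory(t, x, y, config, shock=None, **meta):
    """Trajectory from raw arrays with defaulted metadata."""
    t = np.asarray(t, float)
    shock = np.zeros(len(t), bool) if shock is None else shock
    meta.setdefault("animal_id", "test")
    meta.setdefault("group", "control")
    meta.setdefault("session", 1)
    return Trajectory(t=t, x=np.asarray(x, float), y=np.asarray(y, float),
                      shock=shock, **meta)


def circular_path(radius, angular_speed, duration, config, phi0=0.0, fs=None):
    """Uniform circular motion in the ROOM frame as a whole-path segment."""
    fs = fs or config.sampling_rate
    t = np.arange(int(round(duration * fs))) / fs
    phi = phi0 + angular_speed * t
    traj = make_trajectory(t, radius * np.cos(phi), radius * np.sin(phi), config)
    return Segment(traj, 0, len(t) - 1, config, stage=1)


def path_segment(t, x, y, config, stage=1):
    traj = make_trajectory(t, x, y, config)
    return Segment(traj, 0, len(t) - 1, config, stage=stage)
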