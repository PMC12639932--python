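"""Shared fixtures: one simulation per mechanism, reused across tests."""

import numpy as np
import pytest

from jointaxis.synthetic_models import (
    BallJointConfig,
    PendulumConfig,
    ball_joint,
    default_squat_parent_excursion,
    double_pendulum,
    planar_custom_joint,
)
from jointaxis.workflows import knee_study_config


@pytest.fixture(scope="session")
def pendulum():
    """Default 10 s / 100 Hz pendulum run: (parent, child, truth)."""
    return double_pendulum(PendulumConfig())


@pytest.fixture(scope="session")
def ball():
    """Ball joint with both segments moving: (parent, child, truth)."""
    cfg = BallJointConfig(parent_excursion=default_squat_parent_excursion())
    return ball_joint(cfg)


@pytest.fixture(scope="session")
def knee():
    """Knee-like planar custom joint, single squat sweep."""
    return planar_custom_joint()


@pytest.fixture(scope="session")
def knee_trial():
    """Knee-like joint driven by the three-cycle calibration trial."""
    return planar_custom_joint(knee_study_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
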