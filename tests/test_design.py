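"""Design enumeration and stimulus kinematics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from flowpred.design import (
    BALL_SPEEDS,
    EXTRA_STATIC_OCCLUSIONS,
    OCCLUSIONS,
    MotionProfile,
    SelfMotionKinematics,
    TrialSpec,
    design_frame,
    enumerate_prediction_trials,
    enumerate_staircase_conditions,
    observer_displacement,
    observer_velocity,
    occluded_distance,
    retinal_speed_stats,
)


@pytest.mark.parametrize("repetitions,expected", [(5, 225), (0, 0), (13, 585), (1, 45)])
def test_prediction_trial_count(repetitions, expected):
    """(27 self-motion cells + 18 static-only cells) x repetitions trials."""
    trials = enumerate_prediction_trials(repetitions)
    assert len(trials) == expected


def test_prediction_design_composition():
    trials = enumerate_prediction_trials(5, rng=1)
    df = design_frame(trials)
    # every (speed, profile, occlusion) cell of the core design has 5 reps
    core = df[df["occlusion"].isin(OCCLUSIONS)]
    counts = core.groupby(["ball_speed", "profile", "occlusion"]).size()
    assert len(counts) == 27 and (counts == 5).all()
    # extra occlusions exist only in the static profile
    extra = df[~df["occlusion"].isin(OCCLUSIONS)]
    assert set(extra["profile"]) == {"static"}
    assert set(extra["occlusion"]) == set(EXTRA_STATIC_OCCLUSIONS)
    # directions near-balanced within each condition
    by_dir = core.groupby(["ball_speed", "profile", "occlusion"])["direction"].sum()
    assert by_dir.abs().max() <= 1


def test_trial_order_is_seeded_shuffle():
    a = enumerate_prediction_trials(5, rng=7)
    b = enumerate_prediction_trials(5, rng=7)
    c = enumerate_prediction_trials(5, rng=8)
    assert a == b
    assert a != c and sorted(map(repr, a)) == sorted(map(repr, c))


def test_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        enumerate_prediction_trials(-1)
    with pytest.raises(ValueError):
        enumerate_prediction_trials(2, extra_occlusions=[0.3, -0.1])
    with pytest.raises(ValueError):
        occluded_distance(0.5, 0.0)
    with pytest.raises(ValueError):
        TrialSpec(4.0, 2, MotionProfile.STATIC, 0.5)


@pytest.mark.parametrize(
    "occlusion,speed,expected", [(0.5, 4, 2.0), (1.0, 6, 6.0), (0.7, 5, 3.5)]
)
def test_occluded_distance(occlusion, speed, expected):
    assert occluded_distance(occlusion, speed) == pytest.approx(expected)


def test_occluded_distance_identity_for_all_design_trials():
    for t in enumerate_prediction_trials(2, rng=0):
        assert t.occluded_distance == t.occlusion * t.ball_speed  # exact


def test_observer_velocity_profile():
    assert observer_velocity(0.25) == pytest.approx(4.0)
    assert observer_velocity(0.0) == pytest.approx(0.0, abs=1e-9)
    assert observer_velocity(0.1) == pytest.approx(4.0)  # plateau
    with pytest.raises(ValueError):
        observer_velocity(0.6)
    with pytest.raises(ValueError):
        observer_velocity(-0.01)


def test_velocity_symmetric_about_midpoint():
    kin = SelfMotionKinematics()
    t = np.linspace(0, 0.5, 101)
    np.testing.assert_allclose(kin.velocity(t), kin.velocity(0.5 - t), atol=1e-12)


def test_displacement_is_1p8_m():
    assert observer_displacement() == pytest.approx(1.8, abs=1e-3)


@pytest.mark.parametrize("sigma_factor", [2.0, 3.0, 4.0, 6.0, 10.0])
def test_displacement_invariant_to_ramp_shape(sigma_factor):
    """Any symmetric monotone ramp yields the same 1.8 m displacement."""
    kin = SelfMotionKinematics(ramp_sigma_factor=sigma_factor)
    assert observer_displacement(kin) == pytest.approx(1.8, abs=0.01)


def _oracle_retinal_stats(speed, profile, occlusion, dt=1e-4):
    """Independent finite-difference computation of the gaze geometry."""
    kin = SelfMotionKinematics()
    n = int(round(0.5 / dt))
    t = np.arange(n + 1) * dt
    x_ball = -speed * 0.25 + speed * t
    sign = {"static": 0, "same": 1, "opposite": -1}[profile]
    v_obs = np.array([float(kin.velocity(min(ti, 0.5))) for ti in t])
    disp = np.concatenate(([0.0], np.cumsum((v_obs[1:] + v_obs[:-1]) / 2 * dt)))
    theta = np.degrees(np.arctan2(x_ball - sign * disp, 8.0))
    return float(np.mean(np.abs(np.diff(theta) / dt)))


@pytest.mark.parametrize("speed", BALL_SPEEDS)
def test_retinal_speed_ordering_and_oracle(speed):
    """Mean |retinal speed|: opposite > static > same, matching a
    brute-force finite-difference oracle."""
    means = {}
    for profile in MotionProfile:
        trial = TrialSpec(speed, +1, profile, 0.5)
        mean_abs, _ = retinal_speed_stats(trial)
        means[profile.value] = mean_abs
        assert mean_abs == pytest.approx(
            _oracle_retinal_stats(speed, profile.value, 0.5), rel=1e-3
        )
    assert means["opposite"] > means["static"] > means["same"]


def test_negligible_retinal_speed_without_relative_motion():
    trial = TrialSpec(1e-9, +1, MotionProfile.STATIC, 0.5)
    mean_abs, extent = retinal_speed_stats(trial)
    assert mean_abs < 1e-6 and extent < 1e-6


def test_angular_extent_within_60_degrees():
    """Every design trajectory, occluded part included, spans <= 60 deg."""
    extents = []
    for t in enumerate_prediction_trials(1, rng=0):
        _, extent = retinal_speed_stats(t, dt=1e-3)
        extents.append(extent)
    assert max(extents) <= 60.0


def test_staircase_conditions():
    conds = enumerate_staircase_conditions()
    assert len(conds) == 18
    assert len(set(conds)) == 18  # unique under (speed, profile, sign)
    static = [c for c in conds if c.profile is MotionProfile.STATIC]
    assert len(static) == 6


@given(
    occ=st.floats(0.05, 2.0, allow_nan=False),
    speed=st.floats(0.5, 10.0, allow_nan=False),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_occluded_distance_product_property(occ, speed):
    assert occluded_distance(occ, speed) == pytest.approx(occ * speed, rel=1e-12)
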