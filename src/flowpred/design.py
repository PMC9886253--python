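"""Experimental design and stimulus kinematics.

The experiment shows a ball travelling laterally at 8 m viewing distance at
one of three speeds (4, 5, 6 m/s) while the observer either stays put or is
translated laterally (visually simulated) in the same or the opposite
direction as the ball.  This module enumerates the trial lists for both
tasks and computes the stimulus kinematics that the generative observer
model and the sanity checks need: the observer's velocity profile, retinal
speeds, and the angular extent of each trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "MotionProfile",
    "TrialSpec",
    "SelfMotionKinematics",
    "StaircaseCondition",
    "BALL_SPEEDS",
    "OCCLUSIONS",
    "EXTRA_STATIC_OCCLUSIONS",
    "enumerate_prediction_trials",
    "enumerate_staircase_conditions",
    "occluded_distance",
    "observer_velocity",
    "observer_displacement",
    "retinal_speed_stats",
    "design_frame",
]

#: Ball speeds used in both tasks (m/s).
BALL_SPEEDS: tuple[float, ...] = (4.0, 5.0, 6.0)

#: Occlusion durations used in all three motion profiles (s).
OCCLUSIONS: tuple[float, ...] = (0.5, 0.6, 0.7)

#: Additional occlusion durations presented only while the observer is
#: static, to map how timing variability scales with occlusion duration.
#: Six durations so that the full design comes to (27 + 18) cells.
EXTRA_STATIC_OCCLUSIONS: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.8, 0.9)

VIEWING_DISTANCE = 8.0  #: m, depth of the ball's path
VISIBLE_DURATION = 0.5  #: s, time the ball is visible
BALL_DIAMETER = 0.4  #: m


class MotionProfile(str, Enum):
    """Self-motion condition while the ball is visible.

    ``static`` is the reference level in every statistical contrast.
    """

    STATIC = "static"
    SAME = "same"
    OPPOSITE = "opposite"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class TrialSpec:
    """One prediction-task trial.

    The visible part of the trajectory is centred in front of the
    observer's starting position; the target rectangle sits at the end of
    the occluded segment, ``occluded_distance = ball_speed * occlusion``
    beyond the point of disappearance.
    """

    ball_speed: float  # m/s
    direction: int  # +1 rightward, -1 leftward
    profile: MotionProfile
    occlusion: float  # s
    viewing_distance: float = VIEWING_DISTANCE
    visible_duration: float = VISIBLE_DURATION
    ball_diameter: float = BALL_DIAMETER

    def __post_init__(self) -> None:
        if self.ball_speed <= 0:
            raise ValueError(f"ball_speed must be positive, got {self.ball_speed}")
        if self.occlusion <= 0:
            raise ValueError(f"occlusion must be positive, got {self.occlusion}")
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")

    @property
    def occluded_distance(self) -> float:
        """Distance between point of disappearance and target (m)."""
        return occluded_distance(self.occlusion, self.ball_speed)


def occluded_distance(occlusion: float, ball_speed: float) -> float:
    """Occluded travel distance: ``occlusion * ball_speed`` (m).

    This is the distance the participant has to extrapolate over in the
    prediction task.
    """
    if occlusion <= 0 or ball_speed <= 0:
        raise ValueError("occlusion and ball_speed must both be positive")
    return occlusion * ball_speed


@dataclass(frozen=True)
class SelfMotionKinematics:
    """Lateral self-motion velocity profile.

    The speed ramps up smoothly over the first ``ramp_duration`` seconds to
    ``peak_speed``, stays constant on the plateau, and ramps back down over
    the final ``ramp_duration``, for 1.8 m of travel over the 500 ms
    visibility window.  The ramp is the CDF of a Gaussian with
    ``sigma = ramp_duration / ramp_sigma_factor``, truncated to the ramp
    window and rescaled to [0, peak]; being symmetric, each ramp
    contributes exactly ``peak_speed * ramp_duration / 2`` of displacement
    regardless of ``sigma``.
    """

    peak_speed: float = 4.0  # m/s
    ramp_duration: float = 0.05  # s
    plateau_duration: float = 0.4  # s
    ramp_sigma_factor: float = 4.0

    @property
    def total_duration(self) -> float:
        return 2 * self.ramp_duration + self.plateau_duration

    def velocity(self, t: float | np.ndarray) -> float | np.ndarray:
        """Observer speed at time ``t`` within [0, total_duration] (m/s)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < -1e-12) or np.any(t_arr > self.total_duration + 1e-12):
            raise ValueError("t outside the self-motion window")
        out = np.full(t_arr.shape, self.peak_speed)
        r, T = self.ramp_duration, self.total_duration
        # mirror the down-ramp onto the up-ramp; profile symmetric about T/2
        tt = np.where(t_arr > T / 2, T - t_arr, t_arr)
        on_ramp = tt < r
        sigma = r / self.ramp_sigma_factor
        lo, hi = norm.cdf(-r / 2, scale=sigma), norm.cdf(r / 2, scale=sigma)
        frac = (norm.cdf(tt[on_ramp] - r / 2, scale=sigma) - lo) / (hi - lo)
        out[on_ramp] = self.peak_speed * frac
        if np.isscalar(t):
            return float(out)
        return out


def observer_velocity(t: float | np.ndarray, kin: SelfMotionKinematics | None = None):
    """Observer speed at time ``t`` (m/s); see :class:`SelfMotionKinematics`."""
    kin = kin or SelfMotionKinematics()
    return kin.velocity(t)


def observer_displacement(kin: SelfMotionKinematics | None = None, dt: float = 1e-4) -> float:
    """Total lateral displacement over the visibility window (m).

    Numeric trapezoidal integral of the velocity profile; 1.8 m for the
    default kinematics (4 m/s peak, 50 ms ramps, 400 ms plateau).
    """
    kin = kin or SelfMotionKinematics()
    t = np.arange(0.0, kin.total_duration + dt / 2, dt)
    return float(np.trapezoid(kin.velocity(t), t))


def _profile_sign(profile: MotionProfile) -> int:
    """Observer direction relative to the ball direction."""
    return {MotionProfile.STATIC: 0, MotionProfile.SAME: 1, MotionProfile.OPPOSITE: -1}[
        MotionProfile(profile)
    ]


def retinal_speed_stats(
    trial: TrialSpec, kin: SelfMotionKinematics | None = None, dt: float = 1e-4
) -> tuple[float, float]:
    """Mean absolute retinal speed and angular extent of a trial.

    Gaze is locked straight ahead in the (translating) head frame and the
    ball stays at constant depth, so the ball's direction is
    ``theta(t) = atan((x_ball - x_observer) / viewing_distance)``.

    Returns
    -------
    mean_abs_retinal_speed : float
        Mean of ``|d theta / dt|`` over the 0.5 s visible window (deg/s).
    angular_extent : float
        Angle spanned by the full trajectory, occluded segment included,
        relative to the observer (deg).  The observer only translates while
        the ball is visible.
    """
    kin = kin or SelfMotionKinematics()
    v, d = trial.ball_speed, trial.direction
    vis = trial.visible_duration
    sign = _profile_sign(trial.profile)

    # visible window
    t = np.arange(0.0, vis + dt / 2, dt)
    x_ball = -d * v * vis / 2 + d * v * t
    vel = kin.velocity(np.minimum(t, kin.total_duration))
    disp = np.concatenate(([0.0], np.cumsum((vel[1:] + vel[:-1]) / 2 * np.diff(t))))
    x_obs = sign * d * disp
    theta = np.degrees(np.arctan2(x_ball - x_obs, trial.viewing_distance))
    dtheta = np.diff(theta) / np.diff(t)
    mean_abs = float(np.mean(np.abs(dtheta)))

    # occluded continuation: observer parked at final displacement
    t_occ = np.arange(dt, trial.occlusion + dt / 2, dt)
    x_ball_occ = x_ball[-1] + d * v * t_occ
    theta_occ = np.degrees(np.arctan2(x_ball_occ - x_obs[-1], trial.viewing_distance))
    full = np.concatenate([theta, theta_occ])
    extent = float(full.max() - full.min())
    return mean_abs, extent


@dataclass(frozen=True)
class StaircaseCondition:
    """One speed-estimation staircase: ball speed x profile x start sign."""

    ball_speed: float
    profile: MotionProfile
    start_sign: int  # +1: starts 30% above the reference, -1: 30% below

    def __post_init__(self) -> None:
        if self.start_sign not in (-1, 1):
            raise ValueError("start_sign must be +1 or -1")


def enumerate_staircase_conditions(
    ball_speeds: Sequence[float] = BALL_SPEEDS,
    profiles: Sequence[MotionProfile] = tuple(MotionProfile),
) -> list[StaircaseCondition]:
    """All staircase conditions: 3 speeds x 3 profiles x 2 start signs = 18."""
    return [
        StaircaseCondition(v, MotionProfile(p), s)
        for v in ball_speeds
        for p in profiles
        for s in (+1, -1)
    ]


def enumerate_prediction_trials(
    repetitions: int,
    extra_occlusions: Iterable[float] = EXTRA_STATIC_OCCLUSIONS,
    rng: np.random.Generator | int | None = 0,
) -> list[TrialSpec]:
    """Full prediction-task trial list in a seeded shuffled order.

    The design crosses 3 ball speeds x 3 motion profiles x 3 occlusion
    durations, plus static-only cells at 3 speeds x ``extra_occlusions``,
    each repeated ``repetitions`` times.  With the default six extra
    occlusions that is (27 + 18) x repetitions trials: 225 at 5 repetitions,
    585 at 13.  Directions alternate left/right within each condition so
    both occur in (near-)equal counts.
    """
    if repetitions < 0:
        raise ValueError("repetitions must be non-negative")
    extra = tuple(extra_occlusions)
    if any(o <= 0 for o in extra):
        raise ValueError("occlusion durations must be positive")

    cells: list[tuple[float, MotionProfile, float]] = [
        (v, MotionProfile(p), o)
        for v in BALL_SPEEDS
        for p in MotionProfile
        for o in OCCLUSIONS
    ]
    cells += [(v, MotionProfile.STATIC, o) for v in BALL_SPEEDS for o in extra]

    trials = [
        TrialSpec(ball_speed=v, direction=1 if r % 2 == 0 else -1, profile=p, occlusion=o)
        for (v, p, o) in cells
        for r in range(repetitions)
    ]
    if rng is not None:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        order = gen.permutation(len(trials))
        trials = [trials[i] for i in order]
    return trials


def design_frame(trials: Sequence[TrialSpec]) -> pd.DataFrame:
    """Tabulate a trial list (one row per trial, CSV-ready)."""
    return pd.DataFrame(
        {
            "trial_id": np.arange(len(trials)),
            "ball_speed": [t.ball_speed for t in trials],
            "direction": [t.direction for t in trials],
            "profile": [t.profile.value for t in trials],
            "occlusion": [t.occlusion for t in trials],
            "occluded_distance": [t.occluded_distance for t in trials],
        }
    )
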