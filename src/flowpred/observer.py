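"""Generative observer model for both tasks.

One set of participant parameters drives both the prediction task and the
speed-estimation task:

* ``b_i`` — additive speed-overestimation bias when the observer translates
  opposite to the ball, expressed as a fraction of the self-motion speed
  (population mean 0.20, between-participant SD 0.30).
* ``p_i`` — fractional inflation of the speed-noise SD in the opposite
  profile (mean 0.20, SD 0.30).
* ``w_i`` — Weber fraction of speed perception (mean 0.10, SD 0.015,
  floored at 0.01).

Perceived ball speed is Normal(mu, w_i * mu * (1 + p_i * [opposite])) with
mu = v + b_i * v_self * [opposite] (Weber noise scales with the mean
percept; see docs/methods.md).  In the prediction task the occluded
distance is perceived with a 5% Weber fraction and the response time is the
perceived distance divided by the perceived speed (d = v * t).  In the 2IFC
task the ball-cloud interval carries no self-motion and is the controlled
comparison: it is unbiased and noise-free by default
(``cloud_weber_scale``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import MotionProfile, TrialSpec, StaircaseCondition
from .staircase import PestConfig, PestState, pest_init, pest_update

__all__ = [
    "PopulationParams",
    "ParticipantParams",
    "sample_participant",
    "perceived_speed",
    "extrapolated_time",
    "simulate_prediction_session",
    "simulate_2ifc_choice",
    "simulate_speed_session",
    "head_rotation_bins",
]

SPEED_FLOOR = 0.05  # m/s, truncation of perceived speeds
WEBER_FLOOR = 0.01  # lowest admissible speed Weber fraction


@dataclass(frozen=True)
class PopulationParams:
    """Population-level parameters of the generative model (defaults = study values)."""

    bias_fraction_mean: float = 0.20
    bias_fraction_sd: float = 0.30
    precision_fraction_mean: float = 0.20
    precision_fraction_sd: float = 0.30
    weber_speed_mean: float = 0.10
    weber_speed_sd: float = 0.015
    weber_distance: float = 0.05
    self_motion_speed: float = 4.0  # m/s
    #: weight of the bias/precision effect in the same-direction profile
    #: (0 by default: effects are modelled for the opposite profile only).
    same_direction_weight: float = 0.0
    #: base of the Weber speed noise: "perceived" scales the noise SD with
    #: the mean perceived (bias-shifted) speed, "physical" with the
    #: presented speed.  See the methods note for why "perceived" is the
    #: default.
    noise_base: str = "perceived"
    #: scale of the Weber noise on the comparison (ball-cloud) percept,
    #: as a multiple of the participant's speed Weber fraction.  0 treats
    #: the controlled comparison as noise-free, so the fitted JND reflects
    #: the single-ball percept's SD directly.
    cloud_weber_scale: float = 0.0

    def __post_init__(self) -> None:
        if min(self.bias_fraction_sd, self.precision_fraction_sd, self.weber_speed_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.weber_speed_mean < 0 or self.weber_distance < 0:
            raise ValueError("Weber fractions must be non-negative")

    def null(self) -> "PopulationParams":
        """Copy with all self-motion effects removed (for type-I calibration)."""
        return replace(
            self,
            bias_fraction_mean=0.0,
            bias_fraction_sd=0.0,
            precision_fraction_mean=0.0,
            precision_fraction_sd=0.0,
        )


@dataclass(frozen=True)
class ParticipantParams:
    """Per-participant draw; the SAME object drives both tasks."""

    id: int
    b: float  # bias fraction of self-motion speed
    p: float  # precision-inflation fraction
    w: float  # speed Weber fraction

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("Weber fraction must be positive")


def sample_participant(
    pop: PopulationParams, rng: np.random.Generator, id: int = 0
) -> ParticipantParams:
    """Draw one participant; the Weber fraction is floored at 0.01."""
    b = rng.normal(pop.bias_fraction_mean, pop.bias_fraction_sd)
    p = rng.normal(pop.precision_fraction_mean, pop.precision_fraction_sd)
    w = max(rng.normal(pop.weber_speed_mean, pop.weber_speed_sd), WEBER_FLOOR)
    return ParticipantParams(id=id, b=b, p=p, w=w)


def _effect_weight(profile: MotionProfile | str, pop: PopulationParams) -> float:
    profile = MotionProfile(profile)
    if profile is MotionProfile.OPPOSITE:
        return 1.0
    if profile is MotionProfile.SAME:
        return pop.same_direction_weight
    return 0.0


def perceived_mean_sd(
    v: float | np.ndarray,
    profile: MotionProfile | str,
    part: ParticipantParams,
    pop: PopulationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD of the perceived-speed distribution (noise-free accessors)."""
    v = np.asarray(v, dtype=float)
    wgt = _effect_weight(profile, pop)
    mean = v + part.b * pop.self_motion_speed * wgt
    base = mean if pop.noise_base == "perceived" else v
    sd = part.w * np.maximum(base, SPEED_FLOOR) * (1.0 + part.p * wgt)
    return mean, np.maximum(sd, 0.0)


def perceived_speed(
    v: float | np.ndarray,
    profile: MotionProfile | str,
    part: ParticipantParams,
    pop: PopulationParams,
    rng: np.random.Generator,
) -> float | np.ndarray:
    """One draw of perceived ball speed (m/s), floored at 0.05 m/s."""
    if np.any(np.asarray(v) <= 0):
        raise ValueError("speeds must be positive")
    mean, sd = perceived_mean_sd(v, profile, part, pop)
    draw = rng.normal(mean, sd)
    out = np.maximum(draw, SPEED_FLOOR)
    return float(out) if np.isscalar(v) else out


def extrapolated_time(
    d: float | np.ndarray,
    v_perceived: float | np.ndarray,
    pop: PopulationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Perceived occluded distance and the extrapolated travel time.

    ``d_perceived ~ Normal(d, weber_distance * d)`` truncated positive;
    ``t = d_perceived / v_perceived``.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    d_perc = np.maximum(rng.normal(d, pop.weber_distance * d), 1e-6)
    t = d_perc / np.asarray(v_perceived, dtype=float)
    return d_perc, t


def simulate_prediction_session(
    part: ParticipantParams,
    design: Sequence[TrialSpec],
    pop: PopulationParams,
    rng: np.random.Generator,
    head_bins: int = 0,
    head_sd_deg: float = 1.0,
) -> pd.DataFrame:
    """Simulate one participant's prediction session (one row per trial).

    The returned frame carries the trial descriptors plus ``v_perceived``,
    ``d_perceived``, ``t_extrapolated``, ``timing_error`` (extrapolated
    minus true occlusion) and ``response_time`` (time of the button press
    measured from the moment the ball disappears, equal to the extrapolated
    time under the model).  With ``head_bins > 0``, per-trial head-rotation
    bin columns ``head_bin_*`` are added (compliant by default:
    Normal(0, 1 deg)).
    """
    v = np.array([t.ball_speed for t in design])
    occ = np.array([t.occlusion for t in design])
    dist = v * occ
    profiles = np.array([t.profile.value for t in design])

    wgt = np.zeros(len(design))
    for prof in MotionProfile:
        wgt[profiles == prof.value] = _effect_weight(prof, pop)
    mean = v + part.b * pop.self_motion_speed * wgt
    base = np.maximum(mean, SPEED_FLOOR) if pop.noise_base == "perceived" else v
    sd = np.maximum(part.w * base * (1.0 + part.p * wgt), 0.0)
    v_perc = np.maximum(rng.normal(mean, sd), SPEED_FLOOR)
    d_perc, t_ext = extrapolated_time(dist, v_perc, pop, rng)

    out = pd.DataFrame(
        {
            "participant": part.id,
            "trial_id": np.arange(len(design)),
            "ball_speed": v,
            "direction": [t.direction for t in design],
            "profile": profiles,
            "occlusion": occ,
            "occluded_distance": dist,
            "v_perceived": v_perc,
            "d_perceived": d_perc,
            "t_extrapolated": t_ext,
            "timing_error": t_ext - occ,
            "response_time": t_ext,
        }
    )
    if head_bins > 0:
        bins = head_rotation_bins(len(design), head_bins, rng, sd_deg=head_sd_deg)
        for j in range(head_bins):
            out[f"head_bin_{j}"] = bins[:, j]
    return out


def head_rotation_bins(
    n_trials: int,
    n_bins: int,
    rng: np.random.Generator,
    sd_deg: float = 1.0,
    offset_deg: float = 0.0,
) -> np.ndarray:
    """Per-trial mean head rotations over recording bins (deg).

    Compliant participants keep the head within +-2.5 deg of straight
    ahead; ``offset_deg`` shifts the distribution to emulate
    non-compliance for testing the exclusion filter.
    """
    return rng.normal(offset_deg, sd_deg, size=(n_trials, n_bins))


def simulate_2ifc_choice(
    ball_speed: float,
    profile: MotionProfile | str,
    cloud_speed: float,
    part: ParticipantParams,
    pop: PopulationParams,
    rng: np.random.Generator,
) -> bool:
    """Judge which interval was faster: True if the cloud is chosen.

    The single-ball interval is perceived under the self-motion profile;
    the cloud interval carries no self-motion, so it is perceived without
    bias and (by default) without noise — ``pop.cloud_weber_scale`` adds
    Weber noise as a multiple of the participant's fraction.
    """
    if ball_speed <= 0 or cloud_speed <= 0:
        raise ValueError("speeds must be positive")
    ball_perc = perceived_speed(ball_speed, profile, part, pop, rng)
    w_cloud = pop.cloud_weber_scale * part.w
    cloud_perc = max(rng.normal(cloud_speed, w_cloud * cloud_speed), SPEED_FLOOR)
    return bool(cloud_perc > ball_perc)


def simulate_speed_session(
    part: ParticipantParams,
    conditions: Sequence[StaircaseCondition],
    pop: PopulationParams,
    rng: np.random.Generator,
    pest_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Run every staircase of a speed-estimation session to termination.

    Returns one row per 2IFC trial: staircase id, condition descriptors,
    presented cloud speed, response and staircase bookkeeping.  With the
    default termination rules each of the 18 staircases takes between 30
    and 37 trials (540 to 666 per session).
    """
    pest_kwargs = pest_kwargs or {}
    rows: list[tuple] = []
    for sc_id, cond in enumerate(conditions):
        cfg = PestConfig(reference_speed=cond.ball_speed, **pest_kwargs)
        state = pest_init(cfg, cond.start_sign)
        while not state.terminated:
            level = state.level
            resp = simulate_2ifc_choice(cond.ball_speed, cond.profile, level, part, pop, rng)
            pest_update(state, cfg, resp)
            rows.append(
                (
                    part.id,
                    sc_id,
                    cond.ball_speed,
                    cond.profile.value,
                    cond.start_sign,
                    state.n_trials - 1,
                    level,
                    resp,
                    state.step,
                    state.terminated,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "staircase_id",
            "ball_speed",
            "profile",
            "start_sign",
            "trial_index",
            "cloud_speed",
            "chose_cloud_faster",
            "step",
            "terminated",
        ],
    )
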