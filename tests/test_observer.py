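"""Generative observer model for both tasks."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from flowpred.design import MotionProfile, enumerate_prediction_trials, enumerate_staircase_conditions
from flowpred.observer import (
    ParticipantParams,
    PopulationParams,
    extrapolated_time,
    perceived_speed,
    sample_participant,
    simulate_2ifc_choice,
    simulate_prediction_session,
    simulate_speed_session,
)

TINY_W = 1e-9  # effectively noise-free Weber fraction


def test_degenerate_draw_returns_means(rng):
    pop = PopulationParams(bias_fraction_sd=0, precision_fraction_sd=0, weber_speed_sd=0)
    part = sample_participant(pop, rng)
    assert (part.b, part.p, part.w) == (0.20, 0.20, 0.10)


def test_moment_recovery_over_10000_draws(pop):
    rng = np.random.default_rng(99)
    draws = [sample_participant(pop, rng) for _ in range(10_000)]
    b = np.array([d.b for d in draws])
    w = np.array([d.w for d in draws])
    assert b.mean() == pytest.approx(0.20, abs=0.01)
    assert w.std() == pytest.approx(0.015, abs=0.002)
    assert w.min() >= 0.01  # truncation floor


def test_perceived_speed_noise_free_limits(pop, rng):
    part = ParticipantParams(0, b=0.20, p=0.20, w=TINY_W)
    assert perceived_speed(4.0, "static", part, pop, rng) == pytest.approx(4.0, abs=1e-6)
    assert perceived_speed(4.0, "opposite", part, pop, rng) == pytest.approx(4.8, abs=1e-6)
    with pytest.raises(ValueError):
        perceived_speed(-1.0, "static", part, pop, rng)


def test_precision_inflation_is_20_percent(rng):
    """SD of perceived speed is 20% higher in the opposite profile
    (isolated from the bias by setting it to zero)."""
    pop = PopulationParams(bias_fraction_mean=0.0, bias_fraction_sd=0.0)
    part = ParticipantParams(0, b=0.0, p=0.20, w=0.10)
    v = np.full(10_000, 4.0)
    sd_static = np.std(perceived_speed(v, "static", part, pop, rng))
    sd_opp = np.std(perceived_speed(v, "opposite", part, pop, rng))
    assert sd_opp / sd_static == pytest.approx(1.2, abs=0.05)


def test_extrapolated_time_division(pop, rng):
    _, t = extrapolated_time(2.0, 4.0, PopulationParams(weber_distance=0.0), rng)
    assert t == pytest.approx(0.5)


def test_noise_free_timing_errors(pop):
    """Static profile is unbiased; the opposite profile composes the 20%
    bias with d = v*t: at 4 m/s and 0.5 s occlusion the extrapolated time
    is 2.0/4.8 s (~83 ms early)."""
    part = ParticipantParams(0, b=0.20, p=0.20, w=TINY_W)
    noise_free = PopulationParams(weber_distance=0.0)
    design = enumerate_prediction_trials(1, rng=3)
    out = simulate_prediction_session(part, design, noise_free, np.random.default_rng(0))
    static = out[out["profile"] == "static"]
    assert np.allclose(static["timing_error"], 0.0, atol=1e-6)
    opp = out[(out["profile"] == "opposite") & (out["ball_speed"] == 4.0) & (out["occlusion"] == 0.5)]
    assert opp["t_extrapolated"].iloc[0] == pytest.approx(2.0 / 4.8, abs=1e-6)
    assert opp["timing_error"].iloc[0] == pytest.approx(2.0 / 4.8 - 0.5, abs=1e-6)


def test_session_shapes_and_determinism(pop):
    part = ParticipantParams(0, b=0.2, p=0.2, w=0.1)
    design = enumerate_prediction_trials(5, rng=0)
    a = simulate_prediction_session(part, design, pop, np.random.default_rng(11))
    b = simulate_prediction_session(part, design, pop, np.random.default_rng(11))
    assert len(a) == 225
    assert a.equals(b)


def test_opposite_profile_shortens_extrapolation(pop):
    """Mean timing error in the opposite profile is below static at the
    default 20% bias (averaged over a small cohort)."""
    rng = np.random.default_rng(5)
    design = enumerate_prediction_trials(5, rng=1)
    diffs = []
    for i in range(12):
        part = sample_participant(pop, rng, id=i)
        out = simulate_prediction_session(part, design, pop, rng)
        m = out.groupby("profile")["timing_error"].mean()
        diffs.append(m["opposite"] - m["static"])
    assert np.mean(diffs) < 0


def test_null_model_profiles_indistinguishable():
    """With b=p=0 the timing-error distribution is identical across
    profiles (KS test on 10,000 trials)."""
    pop = PopulationParams()
    part = ParticipantParams(0, b=0.0, p=0.0, w=0.1)
    design = enumerate_prediction_trials(45, rng=2)  # 10,125 trials
    out = simulate_prediction_session(part, design, pop, np.random.default_rng(8))
    core = out[out["occlusion"].isin([0.5, 0.6, 0.7])]
    x = core.loc[core["profile"] == "opposite", "timing_error"]
    y = core.loc[core["profile"] == "static", "timing_error"]
    assert ks_2samp(x, y).pvalue > 0.01


def test_bias_monotonically_advances_responses():
    """Raising the population bias strictly lowers the opposite-profile
    mean timing error (checked at 0.0 / 0.2 / 0.4 with a fixed seed)."""
    means = []
    design = enumerate_prediction_trials(10, rng=4)
    for b in (0.0, 0.2, 0.4):
        pop = PopulationParams(bias_fraction_mean=b, bias_fraction_sd=0.0)
        part = ParticipantParams(0, b=b, p=0.2, w=0.1)
        out = simulate_prediction_session(part, design, pop, np.random.default_rng(21))
        means.append(out.loc[out["profile"] == "opposite", "timing_error"].mean())
    assert means[0] > means[1] > means[2]


def test_2ifc_separation_limit(pop):
    part = ParticipantParams(0, b=0.2, p=0.2, w=0.1)
    rng = np.random.default_rng(3)
    sd = part.w * 4.0
    chosen = sum(
        simulate_2ifc_choice(4.0, "static", 4.0 + 10 * sd, part, pop, rng) for _ in range(2000)
    )
    assert chosen / 2000 >= 0.999


def test_2ifc_noise_free_indifference_point(pop, rng):
    """Noise-free observer with the default bias flips its choice exactly
    at cloud = 4.8 m/s in the opposite profile."""
    part = ParticipantParams(0, b=0.20, p=0.20, w=TINY_W)
    assert not simulate_2ifc_choice(4.0, "opposite", 4.79, part, pop, rng)
    assert simulate_2ifc_choice(4.0, "opposite", 4.81, part, pop, rng)


def test_2ifc_choice_probability_nondecreasing(pop):
    part = ParticipantParams(0, b=0.2, p=0.2, w=0.1)
    rng = np.random.default_rng(17)
    levels = np.linspace(2.0, 8.0, 9)
    probs = [
        np.mean([simulate_2ifc_choice(4.0, "opposite", lv, part, pop, rng) for _ in range(2000)])
        for lv in levels
    ]
    assert all(b - a > -0.03 for a, b in zip(probs, probs[1:]))  # MC tolerance


def test_speed_session_trial_totals(pop):
    rng = np.random.default_rng(2)
    part = sample_participant(pop, rng)
    sess = simulate_speed_session(part, enumerate_staircase_conditions(), pop, rng)
    per = sess.groupby("staircase_id").size()
    assert len(per) == 18 and per.between(30, 37).all()
    assert 540 <= len(sess) <= 666


def test_staircase_converges_near_indifference_point(pop):
    """With (almost) no perceptual noise the staircase parks within one
    final step of the biased observer's indifference point."""
    part = ParticipantParams(0, b=0.20, p=0.0, w=TINY_W)
    rng = np.random.default_rng(0)
    conds = [c for c in enumerate_staircase_conditions() if c.profile is MotionProfile.OPPOSITE]
    sess = simulate_speed_session(part, conds, pop, rng)
    for (speed, sign), grp in sess.groupby(["ball_speed", "start_sign"]):
        target = speed + 0.2 * pop.self_motion_speed
        final = grp.sort_values("trial_index").iloc[-1]
        assert abs(final["cloud_speed"] - target) <= max(final["step"], 0.03) + 1e-9
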