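"""Condition summaries, mixed models, LRTs, bootstrap and the suite."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from flowpred.inference import (
    PROFILE_TERM,
    bootstrap_ci,
    fit_link_models,
    fit_lmm,
    fit_lmm_pair,
    lrt,
    participant_differences,
    preregistered_suite,
    summarize_conditions,
)
from flowpred.preprocessing import apply_exclusions
from flowpred.psychometrics import fit_psychometric_table


@pytest.fixture(scope="module")
def filtered(small_dataset):
    pred, speed, _ = apply_exclusions(small_dataset.prediction, small_dataset.speed)
    psych = fit_psychometric_table(speed)
    return pred, speed, psych


def test_summaries_match_two_pass_oracle(filtered):
    pred, _, _ = filtered
    out = summarize_conditions(pred)
    # 5 repetitions per condition pre-exclusion
    assert (out["n"] == 5).all()
    for _, row in out.sample(10, random_state=0).iterrows():
        cell = pred[
            (pred["participant"] == row["participant"])
            & (pred["profile"] == row["profile"])
            & (pred["ball_speed"] == row["ball_speed"])
            & (pred["occlusion"] == row["occlusion"])
        ]["t_extrapolated"].to_numpy()
        mean = sum(cell) / len(cell)
        sd = np.sqrt(sum((x - mean) ** 2 for x in cell) / (len(cell) - 1))
        assert row["mean_t"] == pytest.approx(mean, abs=1e-12)
        assert row["sd_t"] == pytest.approx(sd, abs=1e-12)


def test_constant_times_give_zero_sd():
    pred = pd.DataFrame(
        {
            "participant": 0,
            "profile": "static",
            "ball_speed": 4.0,
            "occlusion": 0.5,
            "t_extrapolated": [0.5] * 4,
            "timing_error": [0.0] * 4,
        }
    )
    out = summarize_conditions(pred)
    assert out["sd_t"].iloc[0] == 0.0 and out["n"].iloc[0] == 4


def test_lmm_degenerate_limit_matches_ols():
    """With (vanishingly small) residual noise and no participant
    structure the mixed-model fixed effects equal OLS."""
    rng = np.random.default_rng(0)
    n = 216  # full profile x speed crossing, 24 repeats
    prof = np.tile(np.repeat(["static", "opposite", "same"], 3), n // 9)
    speed = np.tile([4.0, 5.0, 6.0], n // 3)
    y = 1.0 - 0.3 * (prof == "opposite") + 0.05 * speed + 1e-8 * rng.standard_normal(n)
    data = pd.DataFrame(
        {"participant": np.arange(n) % 8, "profile": prof, "ball_speed": speed, "y": y}
    )
    fit = fit_lmm(data, f"y ~ {PROFILE_TERM} + ball_speed", re_formula="~1")
    ols = smf.ols(f"y ~ {PROFILE_TERM} + ball_speed", data).fit()
    for name in ols.params.index:
        assert fit.fe_params[name] == pytest.approx(ols.params[name], abs=1e-6)


def test_lmm_fits_profile_effect(filtered):
    pred, _, _ = filtered
    fit = fit_lmm(pred, f"timing_error ~ {PROFILE_TERM}", occlusion_intercepts=True)
    assert fit.converged
    assert fit.coef("[T.opposite]") < 0  # default bias shortens extrapolation
    assert fit.fallback in ("occlusion_vc", "occlusion_fixed", "slope_only")


def test_lrt_identical_models_and_definition(filtered):
    _, _, psych = filtered
    psy = psych[psych["converged"]].reset_index(drop=True)
    fit_a = fit_lmm(psy, f"pse ~ {PROFILE_TERM}")
    fit_b = fit_lmm(psy, "pse ~ 1")
    res = lrt(fit_b, fit_a)
    assert res.statistic == pytest.approx(2 * (fit_a.loglik - fit_b.loglik), abs=1e-8)
    assert res.df == 2
    same = lrt(fit_a, fit_a)
    assert same.statistic == pytest.approx(0.0, abs=1e-8)
    assert same.p_value == 1.0


def test_lrt_rejects_reversed_nesting(filtered):
    _, _, psych = filtered
    psy = psych[psych["converged"]].reset_index(drop=True)
    fit_a = fit_lmm(psy, f"pse ~ {PROFILE_TERM}")
    fit_b = fit_lmm(psy, "pse ~ 1")
    with pytest.raises(ValueError):
        lrt(fit_a, fit_b)


def test_pair_fitting_shares_rung(filtered):
    pred, _, _ = filtered
    summaries = summarize_conditions(pred).dropna(subset=["sd_t"])
    prec = summaries[summaries["sd_t"] > 0.01].assign(log_sd=lambda d: np.log(d["sd_t"]))
    test, null = fit_lmm_pair(
        prec, f"log_sd ~ mean_t + {PROFILE_TERM}", "log_sd ~ mean_t",
        occlusion_intercepts=True,
    )
    assert test.fallback == null.fallback
    assert test.loglik >= null.loglik - 1e-6
    assert len(test.fe_params) - len(null.fe_params) == 2


def test_bootstrap_degenerate_and_monotone_width():
    rng = np.random.default_rng(1)

    def mean_y(df):
        return float(df["y"].mean())

    const = pd.DataFrame({"participant": range(6), "y": 2.5})
    ci = bootstrap_ci(const, mean_y, rng, n_boot=50)
    assert (ci.lower, ci.estimate, ci.upper) == (2.5, 2.5, 2.5)

    wide_widths = []
    for n in (20, 40):
        data = pd.DataFrame(
            {"participant": range(n), "y": np.random.default_rng(0).standard_normal(n)}
        )
        ci = bootstrap_ci(data, mean_y, rng, n_boot=400)
        assert ci.lower <= ci.estimate <= ci.upper
        wide_widths.append(ci.upper - ci.lower)
    assert wide_widths[1] < wide_widths[0]


def test_bootstrap_coverage_of_known_mean():
    """Cluster-bootstrap percentile intervals cover a known population
    mean at roughly the nominal 95% rate."""
    rng = np.random.default_rng(2)
    hits = 0
    n_data = 200
    for _ in range(n_data):
        data = pd.DataFrame({"participant": range(25), "y": rng.standard_normal(25)})
        ci = bootstrap_ci(data, lambda d: float(d["y"].mean()), rng, n_boot=200)
        hits += ci.lower <= 0.0 <= ci.upper
    assert hits / n_data == pytest.approx(0.95, abs=0.05)


def test_link_models_perfect_linkage():
    """Noiseless shared mechanism gives R^2 = 1 and the expected signs."""
    b = np.linspace(-0.2, 0.6, 15)
    p = np.sin(np.arange(15.0))  # independent precision spread
    diffs = pd.DataFrame(
        {
            "participant": range(15),
            "pse_diff": 4.0 * b,
            "mean_time_diff": -0.3 * b,
            "jnd_diff": 0.5 * p,
            "sd_time_diff": -0.1 * b - 0.2 * p,
        }
    )
    acc, prec_test, _, link_lrt = fit_link_models(diffs)
    assert acc.rsquared == pytest.approx(1.0, abs=1e-9)
    assert acc.params["pse_diff"] == pytest.approx(-0.075, abs=1e-9)
    assert link_lrt.p_value < 0.05


def test_shuffled_pairing_breaks_linkage(filtered):
    """Permuting the participant pairing leaves the cross-task slope CI
    covering zero in about 95% of reshuffles."""
    rng = np.random.default_rng(3)
    n, sigma = 30, 1.0
    hits = 0
    n_shuffles = 100
    base = pd.DataFrame(
        {
            "participant": range(n),
            "pse_diff": rng.normal(0.8, 1.2, n),
            "mean_time_diff": rng.normal(-0.08, 0.05, n),
        }
    )
    for _ in range(n_shuffles):
        shuffled = base.assign(pse_diff=rng.permutation(base["pse_diff"].to_numpy()))
        fit = smf.ols("mean_time_diff ~ pse_diff", shuffled).fit()
        lo, hi = fit.conf_int().loc["pse_diff"]
        hits += lo <= 0.0 <= hi
    assert hits / n_shuffles == pytest.approx(0.95, abs=0.07)


def test_participant_differences_shapes(filtered):
    pred, _, psych = filtered
    diffs = participant_differences(pred, psych)
    assert set(diffs.columns) == {
        "participant", "mean_time_diff", "sd_time_diff", "pse_diff", "jnd_diff",
    }
    assert len(diffs) == 8


def test_suite_full_and_partial(filtered):
    pred, speed, psych = filtered
    full = preregistered_suite(pred, speed_trials=speed, psych_table=psych, fast=True)
    assert set(full) == {"H1a", "H1b", "H2a", "H2b", "H3a", "H3b"}
    assert all(r.decision in (True, False) for r in full.values())
    assert full["H1a"].estimate < 0 and full["H2a"].estimate > 0

    partial = preregistered_suite(pred, fast=True)
    assert partial["H1a"].decision in (True, False)
    for name in ("H2a", "H2b", "H3a", "H3b"):
        assert partial[name].decision is None
        assert "unavailable" in partial[name].note


def test_suite_bootstrap_route(filtered):
    pred, speed, psych = filtered
    rng = np.random.default_rng(11)
    res = preregistered_suite(
        pred, speed_trials=speed, psych_table=psych,
        method="bootstrap", n_boot=30, rng=rng, fast=True,
    )
    assert res["H1a"].method == "bootstrap"
    assert res["H1a"].ci_lower <= res["H1a"].estimate <= res["H1a"].ci_upper
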