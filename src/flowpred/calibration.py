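"""Two-step per-participant calibration of self-motion bias and precision.

For each participant and task, two dimensionless parameters of the observer
model are recovered from data: the accuracy parameter (speed bias as a
fraction of the self-motion speed) and the precision parameter (fractional
inflation of speed noise).  Fitting is simulation-based and two-step:

1. the precision parameter is pinned at zero and the accuracy parameter is
   found by bounded Brent minimisation of the root median squared error
   (RMedSE) between the observed and simulated (self-motion minus static)
   differences — per (speed, occlusion) mean timing-error differences for
   the prediction task, per-speed PSE differences for the speed task;
2. the accuracy parameter is fixed at its step-1 value and the precision
   parameter is fitted the same way on dispersion differences (SDs of the
   extrapolated time, or JNDs).

Each objective evaluation re-simulates a batch of synthetic sessions with
common random numbers (the noise draws are frozen per fit), which makes the
objective deterministic and smooth enough for Brent.  Because both
parameters are fractions of the same self-motion speed in both tasks, a
regression of prediction-task estimates on speed-task estimates across
participants is expected to have slope ~1 when one set of participant
parameters truly drives both tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.optimize import minimize_scalar

from .design import BALL_SPEEDS, OCCLUSIONS
from .observer import PopulationParams, SPEED_FLOOR
from .psychometrics import fit_cum_gaussian

__all__ = [
    "CalibrationConfig",
    "FittedParam",
    "PredictionTaskSimulator",
    "SpeedTaskSimulator",
    "fit_bias_param",
    "fit_precision_param",
    "observed_prediction_diffs",
    "observed_speed_diffs",
    "calibrate_dataset",
    "cross_task_slope",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Simulation budget and optimiser settings for the two-step fit."""

    n_sim: int = 200  # synthetic sessions per objective evaluation
    reps: int = 13  # prediction-task repetitions per cell and session
    bounds: tuple[float, float] = (-1.0, 2.0)
    xatol: float = 1e-3
    #: dispersion objective: "sd_difference" compares SD(self-motion cell)
    #: minus SD(static cell); "sd_of_differences" uses the SD of the
    #: self-motion timing errors centred on the static cell mean.
    sd_objective: str = "sd_difference"
    n_levels: int = 11  # constant-stimuli probe of the 2IFC model
    level_span: float = 0.40  # probe levels cover reference * (1 +- span)
    trials_per_condition: int = 70  # pooled 2IFC trials per condition/session


@dataclass(frozen=True)
class FittedParam:
    value: float
    objective: float
    at_bound: bool


def fit_bias_param(
    observed: np.ndarray,
    simulate_diffs,
    cfg: CalibrationConfig,
) -> FittedParam:
    """Step 1: Brent minimisation of the RMedSE on accuracy differences."""
    return _brent_rmedse(observed, simulate_diffs, cfg)


def fit_precision_param(
    observed: np.ndarray,
    simulate_diffs,
    cfg: CalibrationConfig,
) -> FittedParam:
    """Step 2: same minimisation on dispersion differences (bias held fixed
    by the caller inside ``simulate_diffs``)."""
    return _brent_rmedse(observed, simulate_diffs, cfg)


def _brent_rmedse(observed, simulate_diffs, cfg: CalibrationConfig) -> FittedParam:
    observed = np.asarray(observed, dtype=float)

    def objective(x: float) -> float:
        resid = observed - simulate_diffs(x)
        return float(np.sqrt(np.median(resid**2)))

    res = minimize_scalar(
        objective, bounds=cfg.bounds, method="bounded", options={"xatol": cfg.xatol}
    )
    x = float(res.x)
    at_bound = min(abs(x - cfg.bounds[0]), abs(x - cfg.bounds[1])) < 2 * cfg.xatol
    return FittedParam(value=x, objective=float(res.fun), at_bound=at_bound)


class PredictionTaskSimulator:
    """Frozen-noise simulator of per-cell timing-error differences.

    Cells are the (ball speed x occlusion) grid shared by the static and
    the self-motion profile.  Nuisance parameters (Weber fractions) are
    fixed at their population means; only the bias and precision fractions
    vary across objective evaluations.
    """

    def __init__(
        self,
        pop: PopulationParams,
        cfg: CalibrationConfig,
        rng: np.random.Generator,
        speeds=BALL_SPEEDS,
        occlusions=OCCLUSIONS,
    ):
        self.pop = pop
        self.cfg = cfg
        cells = [(v, o) for v in speeds for o in occlusions]
        self.cells = cells
        self.v = np.array([c[0] for c in cells])[:, None, None]
        self.occ = np.array([c[1] for c in cells])[:, None, None]
        self.d = self.v * self.occ
        shape = (len(cells), cfg.n_sim, cfg.reps)
        self.z_speed_m = rng.standard_normal(shape)
        self.z_dist_m = rng.standard_normal(shape)
        self.z_speed_s = rng.standard_normal(shape)
        self.z_dist_s = rng.standard_normal(shape)
        self._t_static = self._times(0.0, 0.0, self.z_speed_s, self.z_dist_s, moving=False)

    def _times(self, b, p, z_speed, z_dist, moving: bool) -> np.ndarray:
        w = self.pop.weber_speed_mean
        bias = b * self.pop.self_motion_speed if moving else 0.0
        infl = 1.0 + p if moving else 1.0
        mean = self.v + bias
        base = np.maximum(mean, SPEED_FLOOR) if self.pop.noise_base == "perceived" else self.v
        v_perc = np.maximum(mean + w * base * infl * z_speed, SPEED_FLOOR)
        d_perc = np.maximum(self.d * (1.0 + self.pop.weber_distance * z_dist), 1e-6)
        return d_perc / v_perc

    def mean_diffs(self, b: float, p: float = 0.0) -> np.ndarray:
        """Per-cell mean timing-error difference (self-motion - static)."""
        t_m = self._times(b, p, self.z_speed_m, self.z_dist_m, moving=True)
        return (t_m - self._t_static).mean(axis=(1, 2))

    def sd_diffs(self, b: float, p: float) -> np.ndarray:
        """Per-cell dispersion difference, averaged over sessions."""
        t_m = self._times(b, p, self.z_speed_m, self.z_dist_m, moving=True)
        if self.cfg.sd_objective == "sd_of_differences":
            centred = t_m - self._t_static.mean(axis=2, keepdims=True)
            sd_m = centred.std(axis=2, ddof=1)
            sd_s = (
                self._t_static - self._t_static.mean(axis=2, keepdims=True)
            ).std(axis=2, ddof=1)
        else:
            sd_m = t_m.std(axis=2, ddof=1)
            sd_s = self._t_static.std(axis=2, ddof=1)
        return (sd_m - sd_s).mean(axis=1)


class SpeedTaskSimulator:
    """Frozen-noise simulator of per-speed PSE and JND differences.

    The 2IFC choice model is probed with a constant-stimuli grid of
    comparison levels (rather than re-running the adaptive staircase) and
    the same cumulative-Gaussian fitter used on observed data is applied to
    the simulated choices; the static condition does not depend on the
    fitted parameters and is fitted once.
    """

    def __init__(
        self,
        pop: PopulationParams,
        cfg: CalibrationConfig,
        rng: np.random.Generator,
        speeds=BALL_SPEEDS,
    ):
        self.pop = pop
        self.cfg = cfg
        self.speeds = np.asarray(speeds, dtype=float)
        reps = max(2, round(cfg.n_sim * cfg.trials_per_condition / cfg.n_levels))
        grid = np.linspace(-cfg.level_span, cfg.level_span, cfg.n_levels)
        # levels: (n_speeds, n_levels, reps)
        self.levels = self.speeds[:, None, None] * (1.0 + grid)[None, :, None]
        self.levels = np.broadcast_to(self.levels, (len(speeds), cfg.n_levels, reps)).copy()
        shape = self.levels.shape
        self.z_ball_m = rng.standard_normal(shape)
        self.z_cloud_m = rng.standard_normal(shape)
        self.z_ball_s = rng.standard_normal(shape)
        self.z_cloud_s = rng.standard_normal(shape)
        self._static = self._fit(0.0, 0.0, self.z_ball_s, self.z_cloud_s, moving=False)

    def _fit(self, b, p, z_ball, z_cloud, moving: bool) -> np.ndarray:
        w = self.pop.weber_speed_mean
        v = self.speeds[:, None, None]
        bias = b * self.pop.self_motion_speed if moving else 0.0
        infl = 1.0 + p if moving else 1.0
        mean = v + bias
        base = np.maximum(mean, SPEED_FLOOR) if self.pop.noise_base == "perceived" else v
        ball_perc = np.maximum(mean + w * base * infl * z_ball, SPEED_FLOOR)
        w_cloud = self.pop.cloud_weber_scale * w
        cloud_perc = np.maximum(self.levels * (1.0 + w_cloud * z_cloud), SPEED_FLOOR)
        chose_cloud = cloud_perc > ball_perc
        out = np.empty((len(self.speeds), 2))
        for i, ref in enumerate(self.speeds):
            fit = fit_cum_gaussian(
                self.levels[i].ravel(),
                chose_cloud[i].ravel(),
                sigma_bounds=(1e-3, 3.0 * ref),
                n_starts=2,
            )
            out[i] = (fit.pse, fit.jnd)
        return out

    def pse_diffs(self, b: float, p: float = 0.0) -> np.ndarray:
        moving = self._fit(b, p, self.z_ball_m, self.z_cloud_m, moving=True)
        return moving[:, 0] - self._static[:, 0]

    def jnd_diffs(self, b: float, p: float) -> np.ndarray:
        moving = self._fit(b, p, self.z_ball_m, self.z_cloud_m, moving=True)
        return moving[:, 1] - self._static[:, 1]


def observed_prediction_diffs(
    pred_trials: pd.DataFrame,
    profile: str = "opposite",
    speeds=BALL_SPEEDS,
    occlusions=OCCLUSIONS,
    sd_objective: str = "sd_difference",
) -> tuple[np.ndarray, np.ndarray]:
    """Observed per-cell mean and SD differences for one participant.

    Returns arrays aligned with :class:`PredictionTaskSimulator` cell order
    (speed-major).  Cells with no data in either profile yield NaN.
    """
    mean_diffs, sd_diffs = [], []
    for v in speeds:
        for o in occlusions:
            cell = pred_trials[
                (pred_trials["ball_speed"] == v) & (pred_trials["occlusion"] == o)
            ]
            t_m = cell.loc[cell["profile"] == profile, "t_extrapolated"]
            t_s = cell.loc[cell["profile"] == "static", "t_extrapolated"]
            if len(t_m) < 2 or len(t_s) < 2:
                mean_diffs.append(np.nan)
                sd_diffs.append(np.nan)
                continue
            mean_diffs.append(t_m.mean() - t_s.mean())
            if sd_objective == "sd_of_differences":
                sd_diffs.append((t_m - t_s.mean()).std(ddof=1) - (t_s - t_s.mean()).std(ddof=1))
            else:
                sd_diffs.append(t_m.std(ddof=1) - t_s.std(ddof=1))
    return np.asarray(mean_diffs), np.asarray(sd_diffs)


def observed_speed_diffs(
    psych_table: pd.DataFrame, profile: str = "opposite", speeds=BALL_SPEEDS
) -> tuple[np.ndarray, np.ndarray]:
    """Observed per-speed PSE and JND differences for one participant."""
    pse, jnd = [], []
    for v in speeds:
        sub = psych_table[psych_table["ball_speed"] == v]
        row_m = sub[sub["profile"] == profile]
        row_s = sub[sub["profile"] == "static"]
        if len(row_m) == 1 and len(row_s) == 1:
            pse.append(float(row_m["pse"].iloc[0] - row_s["pse"].iloc[0]))
            jnd.append(float(row_m["jnd"].iloc[0] - row_s["jnd"].iloc[0]))
        else:
            pse.append(np.nan)
            jnd.append(np.nan)
    return np.asarray(pse), np.asarray(jnd)


def _fit_task(observed_acc, observed_disp, sim_acc, sim_disp, cfg) -> dict:
    """Run the enforced two-step fit for one participant and task."""
    ok_acc = np.isfinite(observed_acc)
    bias = fit_bias_param(observed_acc[ok_acc], lambda b: sim_acc(b)[ok_acc], cfg)
    out = {
        "bias_hat": bias.value,
        "bias_objective": bias.objective,
        "bias_at_bound": bias.at_bound,
        "precision_hat": np.nan,
        "precision_objective": np.nan,
        "precision_at_bound": False,
    }
    if observed_disp is not None:
        ok = np.isfinite(observed_disp)
        prec = fit_precision_param(
            observed_disp[ok], lambda p: sim_disp(bias.value, p)[ok], cfg
        )
        out.update(
            precision_hat=prec.value,
            precision_objective=prec.objective,
            precision_at_bound=prec.at_bound,
        )
    return out


def calibrate_dataset(
    prediction_trials: pd.DataFrame,
    psych_table: pd.DataFrame,
    pop: PopulationParams,
    cfg: CalibrationConfig,
    rng: np.random.Generator,
    profile: str = "opposite",
    fit_precision: bool = True,
    tasks: tuple[str, ...] = ("prediction", "speed"),
) -> pd.DataFrame:
    """Fit bias (and optionally precision) per participant and task.

    One shared frozen-noise simulator per task is reused across
    participants (common random numbers), so estimates are deterministic
    given ``rng``'s state at entry.
    """
    pred_sim = PredictionTaskSimulator(pop, cfg, rng) if "prediction" in tasks else None
    speed_sim = SpeedTaskSimulator(pop, cfg, rng) if "speed" in tasks else None

    ids = sorted(
        set(prediction_trials["participant"].unique())
        & set(psych_table["participant"].unique())
        if len(tasks) == 2
        else (
            prediction_trials["participant"].unique()
            if "prediction" in tasks
            else psych_table["participant"].unique()
        )
    )
    rows = []
    for pid in ids:
        if pred_sim is not None:
            mean_d, sd_d = observed_prediction_diffs(
                prediction_trials[prediction_trials["participant"] == pid],
                profile=profile,
                sd_objective=cfg.sd_objective,
            )
            res = _fit_task(
                mean_d,
                sd_d if fit_precision else None,
                pred_sim.mean_diffs,
                pred_sim.sd_diffs,
                cfg,
            )
            rows.append({"participant": pid, "task": "prediction", **res})
        if speed_sim is not None:
            pse_d, jnd_d = observed_speed_diffs(
                psych_table[psych_table["participant"] == pid], profile=profile
            )
            res = _fit_task(
                pse_d,
                jnd_d if fit_precision else None,
                speed_sim.pse_diffs,
                speed_sim.jnd_diffs,
                cfg,
            )
            rows.append({"participant": pid, "task": "speed", **res})
    return pd.DataFrame(rows)


def cross_task_slope(fitted: pd.DataFrame, ci: float = 0.95) -> dict:
    """Across-participant regressions of prediction-task on speed-task
    parameters (accuracy and, when fitted, precision).

    With shared participant parameters and identical scaling in both tasks
    the slopes are expected to be ~1; the 95% CI should contain 1.
    """
    wide = fitted.pivot(index="participant", columns="task")
    out = {}
    for par, key in (("bias_hat", "bias"), ("precision_hat", "precision")):
        if (par, "prediction") not in wide.columns or (par, "speed") not in wide.columns:
            continue
        df = pd.DataFrame(
            {"y": wide[(par, "prediction")], "x": wide[(par, "speed")]}
        ).dropna()
        if len(df) < 3:
            continue
        fit = smf.ols("y ~ x", df).fit()
        lo, hi = fit.conf_int(alpha=1 - ci).loc["x"]
        out[key] = {
            "slope": float(fit.params["x"]),
            "ci_lower": float(lo),
            "ci_upper": float(hi),
            "r_squared": float(fit.rsquared),
            "n": int(len(df)),
        }
    return out
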