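"""Preregistered exclusion rules applied before inference.

Four rules:

(a) prediction trials answered later than three times the occlusion
    duration (measured from the ball's disappearance) are missed trials;
(b) participants whose staircases pinned the comparison speed at the
    staircase limits (reference/3 or 3x reference) on more than 20% of
    2IFC trials are excluded from the speed task;
(c) for precision analyses only, condition cells with an SD (seconds for
    timing, m/s for JNDs) of 0.01 or lower are dropped, since their log
    would dominate the precision regressions;
(d) trials where the head was outside +-2.5 deg of straight ahead for at
    least half of the recorded bins are dropped (both tasks, when head
    recordings are present).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["ExclusionReport", "apply_exclusions", "drop_low_sd", "HEAD_LIMIT_DEG"]

logger = logging.getLogger(__name__)

HEAD_LIMIT_DEG = 2.5
RESPONSE_FACTOR = 3.0
LIMIT_FRACTION = 0.20
SD_FLOOR = 0.01
_LIMIT_TOL = 1e-9


@dataclass
class ExclusionReport:
    """Counts and provenance of every exclusion rule."""

    n_trials_dropped_timeout: int = 0
    participants_excluded_staircase: list = field(default_factory=list)
    n_trials_dropped_staircase: int = 0
    n_conditions_dropped_low_sd: int = 0
    n_trials_dropped_head_prediction: int = 0
    n_trials_dropped_head_speed: int = 0
    timeout_trial_ids: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _head_violations(df: pd.DataFrame) -> np.ndarray | None:
    cols = [c for c in df.columns if c.startswith("head_bin_")]
    if not cols:
        return None
    bins = df[cols].to_numpy(dtype=float)
    outside = np.abs(bins) > HEAD_LIMIT_DEG
    return outside.sum(axis=1) >= np.ceil(bins.shape[1] / 2.0)


def apply_exclusions(
    prediction_trials: pd.DataFrame,
    speed_trials: pd.DataFrame | None = None,
    report: ExclusionReport | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None, ExclusionReport]:
    """Apply rules (a), (b) and (d); rule (c) is applied by the caller on
    the condition summaries / JND tables via :func:`drop_low_sd`.

    Rules are independent (each is computed on the input data), so their
    counts do not depend on application order and the whole filter is
    idempotent.
    """
    report = report or ExclusionReport()

    pred = prediction_trials
    # (a) missed trials: response later than 3x the occlusion duration
    timeout = pred["response_time"] > RESPONSE_FACTOR * pred["occlusion"]
    # (d) head rotation out of range for at least half of the bins
    head_bad = _head_violations(pred)
    if head_bad is None:
        logger.warning("prediction-trial log has no head_bin_* columns; head rule skipped")
        head_bad = np.zeros(len(pred), dtype=bool)
    drop = timeout.to_numpy() | head_bad
    report.n_trials_dropped_timeout = int(timeout.sum())
    report.timeout_trial_ids = pred.loc[timeout, "trial_id"].tolist() if "trial_id" in pred else []
    report.n_trials_dropped_head_prediction = int((head_bad & ~timeout.to_numpy()).sum())
    pred_out = pred.loc[~drop].reset_index(drop=True)

    speed_out = None
    if speed_trials is not None:
        sp = speed_trials
        lower = sp["ball_speed"] / 3.0
        upper = 3.0 * sp["ball_speed"]
        at_limit = (np.abs(sp["cloud_speed"] - lower) <= _LIMIT_TOL) | (
            np.abs(sp["cloud_speed"] - upper) <= _LIMIT_TOL
        )
        frac = at_limit.groupby(sp["participant"]).mean()
        bad_participants = sorted(frac.index[frac > LIMIT_FRACTION].tolist())
        # keep already-recorded exclusions stable under re-application
        report.participants_excluded_staircase = sorted(
            set(report.participants_excluded_staircase) | set(bad_participants)
        )
        drop_sp = sp["participant"].isin(bad_participants).to_numpy()
        head_bad_sp = _head_violations(sp)
        if head_bad_sp is not None:
            report.n_trials_dropped_head_speed = int((head_bad_sp & ~drop_sp).sum())
            drop_sp = drop_sp | head_bad_sp
        else:
            logger.warning("speed-trial log has no head_bin_* columns; head rule skipped")
        report.n_trials_dropped_staircase = int(
            sp["participant"].isin(bad_participants).sum()
        )
        speed_out = sp.loc[~drop_sp].reset_index(drop=True)

    return pred_out, speed_out, report


def drop_low_sd(
    table: pd.DataFrame,
    column: str,
    report: ExclusionReport | None = None,
    floor: float = SD_FLOOR,
) -> pd.DataFrame:
    """Rule (c): drop condition cells whose dispersion is ``floor`` or lower.

    Used on the prediction-task condition summaries (``column='sd_t'``, in
    seconds) and on the JND table (``column='jnd'``, in m/s) before any
    model with a log-dispersion response.
    """
    keep = table[column] > floor
    if report is not None:
        report.n_conditions_dropped_low_sd += int((~keep).sum())
    return table.loc[keep].reset_index(drop=True)
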