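"""Trial-log I/O: CSV schemas for both tasks, validation, dataset folders.

No domain standard exists for psychophysics trial logs, so the interchange
format is plain CSV with documented headers.  A prediction log has one row
per trial (ball speed, direction, motion profile, occlusion duration,
response time, optional head-rotation bins); a speed log has one row per
2IFC trial (staircase id, comparison speed, choice).  Columns that the
analysis derives from the required ones (timing error, occluded distance)
are filled in on read when absent.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .design import MotionProfile

__all__ = [
    "PREDICTION_REQUIRED",
    "SPEED_REQUIRED",
    "read_trial_log",
    "write_dataset",
    "read_dataset",
]

PREDICTION_REQUIRED = (
    "participant",
    "ball_speed",
    "direction",
    "profile",
    "occlusion",
    "response_time",
)
SPEED_REQUIRED = (
    "participant",
    "staircase_id",
    "ball_speed",
    "profile",
    "cloud_speed",
    "chose_cloud_faster",
)
_PROFILES = {p.value for p in MotionProfile}


def read_trial_log(path, schema: str) -> pd.DataFrame:
    """Read and validate a trial-log CSV (``schema`` is "prediction" or "speed").

    Raises ``ValueError`` naming any missing required column or illegal
    motion-profile value; derived columns are added when absent.
    """
    if schema not in ("prediction", "speed"):
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, comment="#")
    required = PREDICTION_REQUIRED if schema == "prediction" else SPEED_REQUIRED
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    bad = sorted(set(df["profile"].astype(str)) - _PROFILES)
    if bad:
        raise ValueError(
            f"{path}: illegal profile value(s) {bad}; allowed: {sorted(_PROFILES)}"
        )
    if schema == "prediction":
        if "t_extrapolated" not in df.columns:
            df["t_extrapolated"] = df["response_time"]
        if "timing_error" not in df.columns:
            df["timing_error"] = df["t_extrapolated"] - df["occlusion"]
        if "occluded_distance" not in df.columns:
            df["occluded_distance"] = df["ball_speed"] * df["occlusion"]
    else:
        df["chose_cloud_faster"] = df["chose_cloud_faster"].astype(bool)
    return df


def write_dataset(dataset, out_dir, config=None, extra_meta: dict | None = None) -> Path:
    """Write a simulated dataset as CSVs plus a parameters YAML.

    Writes ``prediction.csv``, ``speed.csv``, ``participants.csv`` and
    ``params.yaml`` (population parameters, config hash, master seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.prediction.to_csv(out / "prediction.csv", index=False)
    dataset.speed.to_csv(out / "speed.csv", index=False)
    dataset.participants.to_csv(out / "participants.csv", index=False)
    meta: dict = {"seed": dataset.seed}
    if config is not None:
        from .config import config_hash

        meta["config"] = config.to_dict()
        meta["config_hash"] = config_hash(config)
    if extra_meta:
        meta.update(extra_meta)
    with open(out / "params.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return out


def read_dataset(data_dir):
    """Read a dataset folder written by :func:`write_dataset`."""
    from .power import Dataset

    data_dir = Path(data_dir)
    prediction = read_trial_log(data_dir / "prediction.csv", "prediction")
    speed = read_trial_log(data_dir / "speed.csv", "speed")
    participants_path = data_dir / "participants.csv"
    participants = (
        pd.read_csv(participants_path) if participants_path.exists() else pd.DataFrame()
    )
    seed = None
    meta_path = data_dir / "params.yaml"
    if meta_path.exists():
        with open(meta_path) as fh:
            seed = (yaml.safe_load(fh) or {}).get("seed")
    return Dataset(participants=participants, prediction=prediction, speed=speed, seed=seed)
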