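"""Monte-Carlo power analysis and type-I calibration of the test battery.

Each simulation draws a fresh cohort, runs both task simulators end to end
(prediction sessions and adaptive-staircase 2IFC sessions), applies the
preregistered exclusion rules, fits the psychometric functions and runs
the six preregistered decisions with the fast Wald approximation.  Power
per hypothesis is the fraction of simulations in which the test rejects;
forcing every self-motion effect (mean and between-participant SD) to zero
turns the same machinery into a false-positive-rate check.

The design grid mirrors the protocol: 20/30/40 participants, 5/9/13
repetitions per prediction condition, and staircase-length bands of
20-27 / 30-37 / 40-47 trials (on average 50/70/90 2IFC trials per
condition once the two staircases of a condition are pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import binom

from .design import enumerate_prediction_trials, enumerate_staircase_conditions
from .inference import preregistered_suite
from .observer import (
    PopulationParams,
    sample_participant,
    simulate_prediction_session,
    simulate_speed_session,
)
from .preprocessing import apply_exclusions
from .psychometrics import fit_psychometric_table

__all__ = [
    "Dataset",
    "HYPOTHESES",
    "PEST_BANDS",
    "simulate_experiment",
    "analyze_dataset",
    "power_cell",
    "power_grid",
    "type1_calibration",
    "plot_power",
]

HYPOTHESES = ("H1a", "H1b", "H2a", "H2b", "H3a", "H3b")

#: Staircase-length bands of the design grid: (min_trials, max_trials).
PEST_BANDS = {"short": (20, 27), "standard": (30, 37), "long": (40, 47)}


@dataclass
class Dataset:
    """One simulated dual-task dataset (pre-exclusion trial logs)."""

    participants: pd.DataFrame
    prediction: pd.DataFrame
    speed: pd.DataFrame
    seed: int | None = None


def simulate_experiment(
    n_participants: int = 40,
    repetitions: int = 13,
    pest_band: tuple[int, int] = (30, 37),
    pop: PopulationParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    head_bins: int = 0,
) -> Dataset:
    """Simulate a full dual-task experiment.

    One participant-parameter draw drives both of that participant's
    sessions (the shared-parameter contract behind the cross-task
    hypotheses).  Deterministic given ``seed``.
    """
    pop = pop or PopulationParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    conditions = enumerate_staircase_conditions()
    pest_kwargs = {"min_trials": pest_band[0], "max_trials": pest_band[1]}

    part_rows, pred_frames, speed_frames = [], [], []
    for pid, child in enumerate(ss.spawn(n_participants)):
        rng = np.random.default_rng(child)
        part = sample_participant(pop, rng, id=pid)
        part_rows.append({"participant": pid, "b": part.b, "p": part.p, "w": part.w})
        design = enumerate_prediction_trials(repetitions, rng=rng)
        pred_frames.append(
            simulate_prediction_session(part, design, pop, rng, head_bins=head_bins)
        )
        speed_frames.append(
            simulate_speed_session(part, conditions, pop, rng, pest_kwargs=pest_kwargs)
        )
    return Dataset(
        participants=pd.DataFrame(part_rows),
        prediction=pd.concat(pred_frames, ignore_index=True),
        speed=pd.concat(speed_frames, ignore_index=True),
        seed=getattr(ss, "entropy", None),
    )


def analyze_dataset(
    dataset: Dataset,
    alpha: float = 0.05,
    method: str = "wald",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    psych_starts: int = 2,
    fast: bool = False,
):
    """Exclusions + psychometric fits + the six preregistered decisions.

    ``fast=True`` is the reduced-cost route used inside the Monte-Carlo
    power loop (fixed-occlusion mixed-model rung, fewer optimiser starts).
    """
    pred, speed, report = apply_exclusions(dataset.prediction, dataset.speed)
    psych = fit_psychometric_table(speed, n_starts=psych_starts)
    results = preregistered_suite(
        pred,
        speed_trials=speed,
        psych_table=psych,
        alpha=alpha,
        method=method,
        n_boot=n_boot,
        rng=rng,
        report=report,
        fast=fast,
    )
    return results, report


def _one_sim(n_participants, repetitions, band, pop, alpha, child_seed) -> dict:
    ds = simulate_experiment(
        n_participants, repetitions, band, pop, seed=np.random.SeedSequence(child_seed)
    )
    try:
        results, _ = analyze_dataset(ds, alpha=alpha, method="wald", fast=True)
    except Exception:  # a degenerate simulated dataset: count as non-rejection
        return {h: False for h in HYPOTHESES}
    return {h: bool(results[h].decision) for h in HYPOTHESES}


def power_cell(
    n_participants: int,
    repetitions: int,
    pest_band: tuple[int, int],
    pop: PopulationParams | None = None,
    n_sims: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
    n_jobs: int = 1,
) -> dict:
    """Per-hypothesis rejection rates for one cell of the design grid.

    Simulation seeds are spawned from the master seed, so results do not
    depend on the number of workers.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be positive")
    pop = pop or PopulationParams()
    children = [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(seed).spawn(n_sims)]
    rows = Parallel(n_jobs=n_jobs)(
        delayed(_one_sim)(n_participants, repetitions, pest_band, pop, alpha, cs)
        for cs in children
    )
    rates = {h: float(np.mean([r[h] for r in rows])) for h in HYPOTHESES}
    return {
        "n_participants": n_participants,
        "repetitions": repetitions,
        "pest_min": pest_band[0],
        "pest_max": pest_band[1],
        "n_sims": n_sims,
        **rates,
    }


def power_grid(
    ns: Sequence[int] = (20, 30, 40),
    reps: Sequence[int] = (5, 9, 13),
    bands: Sequence[tuple[int, int]] = tuple(PEST_BANDS.values()),
    pop: PopulationParams | None = None,
    n_sims: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Rejection rates over the full design grid (one row per cell)."""
    cells = []
    for i, (n, r, band) in enumerate(
        [(n, r, b) for n in ns for r in reps for b in bands]
    ):
        cells.append(
            power_cell(n, r, band, pop, n_sims=n_sims, alpha=alpha, seed=seed + i, n_jobs=n_jobs)
        )
    return pd.DataFrame(cells)


def type1_calibration(
    n_participants: int = 40,
    repetitions: int = 13,
    pest_band: tuple[int, int] = (30, 37),
    pop: PopulationParams | None = None,
    n_sims: int = 250,
    alpha: float = 0.05,
    seed: int = 0,
    n_jobs: int = 1,
) -> dict:
    """False-positive rates with every self-motion effect forced to zero.

    Rates should be consistent with ``alpha``; the exact binomial 99% band
    around ``alpha`` at the simulated n is reported alongside.
    """
    pop = (pop or PopulationParams()).null()
    cell = power_cell(
        n_participants, repetitions, pest_band, pop,
        n_sims=n_sims, alpha=alpha, seed=seed, n_jobs=n_jobs,
    )
    lo, hi = binom.interval(0.99, n_sims, alpha)
    cell["binomial_99_band"] = (float(lo) / n_sims, float(hi) / n_sims)
    return cell


def plot_power(grid: pd.DataFrame, ax=None):
    """Minimum power across the six tests versus cohort size, one line per
    (repetitions, staircase band) combination."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = grid.assign(min_power=grid[list(HYPOTHESES)].min(axis=1))
    for (r, pmax), sub in grid.groupby(["repetitions", "pest_max"]):
        sub = sub.sort_values("n_participants")
        ax.plot(sub["n_participants"], sub["min_power"], marker="o",
                label=f"{r} reps, <= {pmax} staircase trials")
    for level in (0.8, 0.9, 0.95):
        ax.axhline(level, color="grey", lw=0.5, ls=":")
    ax.set_xlabel("participants")
    ax.set_ylabel("minimum power across the six tests")
    ax.legend(fontsize="small")
    return ax
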