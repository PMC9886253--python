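"""Modified PEST adaptive staircase for the 2IFC speed-estimation task.

The staircase controls the speed of the comparison stimulus (the ball
cloud).  Rules follow classic PEST (halve the step on a reversal; the
second step in a direction equals the first; the fourth and subsequent
same-direction steps double; the third doubles unless the step immediately
preceding the most recent reversal was itself a doubling), with one
modification: for the first ten trials the step is pinned at twice the
initial step size (1.2 m/s) to spread out the sampled levels and stabilise
JND estimates.  Levels are clamped to [reference/3, 3*reference]; a
staircase ends after 37 trials, or once at least 30 trials are done and the
next step would be below 0.03 m/s.

Classic PEST also has a Wald sequential criterion that can delay stepping
until the response counts at the current level deviate reliably from the
target probability; it is off by default (the fixed trial-count bounds
imply per-trial stepping) but available via ``PestConfig.use_wald``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

__all__ = ["PestConfig", "PestState", "pest_init", "pest_update", "pest_terminated", "run_staircase"]


@dataclass(frozen=True)
class PestConfig:
    reference_speed: float  # m/s, speed of the single ball
    start_offset_fraction: float = 0.30
    initial_step: float = 0.6  # m/s
    boost_trials: int = 10  # trials with the step pinned at 2x initial
    min_trials: int = 30
    max_trials: int = 37
    stop_step: float = 0.03  # m/s
    target_probability: float = 0.5
    use_wald: bool = False
    wald_limit: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_speed <= 0:
            raise ValueError("reference_speed must be positive")
        if self.min_trials >= self.max_trials:
            raise ValueError("min_trials must be below max_trials")

    @property
    def boosted_step(self) -> float:
        return 2.0 * self.initial_step

    @property
    def lower_bound(self) -> float:
        return self.reference_speed / 3.0

    @property
    def upper_bound(self) -> float:
        return 3.0 * self.reference_speed


@dataclass
class PestState:
    """Mutable bookkeeping for one running staircase."""

    level: float
    step: float  # magnitude of the next step to apply
    n_trials: int = 0
    direction: int = 0  # direction of the last applied step
    steps_same_direction: int = 0
    last_doubled: bool = False
    double_blocked: bool = False  # suppress the 3rd-step doubling once
    terminated: bool = False
    # Wald-mode bookkeeping: responses at the current level
    n_at_level: int = 0
    n_yes_at_level: int = 0
    history: list[tuple[float, bool]] = field(default_factory=list)


def pest_init(cfg: PestConfig, start_sign: int) -> PestState:
    """Fresh staircase starting 30% above (+1) or below (-1) the reference."""
    if start_sign not in (-1, 1):
        raise ValueError("start_sign must be +1 or -1")
    level = cfg.reference_speed * (1.0 + start_sign * cfg.start_offset_fraction)
    return PestState(level=level, step=cfg.boosted_step)


def pest_terminated(state: PestState, cfg: PestConfig) -> bool:
    """Termination: 37 trials done, or >= 30 trials and next step < 0.03 m/s."""
    return state.n_trials >= cfg.max_trials or (
        state.n_trials >= cfg.min_trials and state.step < cfg.stop_step
    )


def _next_magnitude(state: PestState, cfg: PestConfig, direction: int) -> float:
    """Taylor-Creelman magnitude rules, post-boost, capped at the boosted step."""
    if direction == state.direction:
        k = state.steps_same_direction + 1
        if k == 2:
            mag = state.step
        elif k == 3:
            mag = state.step if state.double_blocked else 2.0 * state.step
        else:
            mag = 2.0 * state.step
        state.steps_same_direction = k
    else:  # reversal
        mag = state.step / 2.0
        state.double_blocked = state.last_doubled
        state.steps_same_direction = 1
    capped = min(mag, cfg.boosted_step)
    state.last_doubled = capped > state.step
    return capped


def pest_update(state: PestState, cfg: PestConfig, response: bool) -> PestState:
    """Record one response ("cloud judged faster") and move the level.

    A "faster" response drives the level down, a "slower" response up,
    homing in on the 50% point.  Mutates ``state`` in place and returns it.
    """
    if state.terminated:
        raise RuntimeError("cannot update a terminated staircase")
    state.history.append((state.level, response))
    state.n_trials += 1
    direction = -1 if response else +1

    if cfg.use_wald:
        state.n_at_level += 1
        state.n_yes_at_level += int(response)
        deviation = state.n_yes_at_level - cfg.target_probability * state.n_at_level
        if abs(deviation) < cfg.wald_limit and state.n_trials < cfg.max_trials:
            # not enough evidence yet: stay at the current level
            state.terminated = pest_terminated(state, cfg)
            return state
        direction = -1 if deviation > 0 else +1
        state.n_at_level = 0
        state.n_yes_at_level = 0

    if state.n_trials <= cfg.boost_trials:
        magnitude = cfg.boosted_step
    elif state.n_trials == cfg.boost_trials + 1:
        # boost phase over: restart the PEST bookkeeping at the initial step
        magnitude = cfg.initial_step
        state.steps_same_direction = 1
        state.last_doubled = False
        state.double_blocked = False
    else:
        magnitude = _next_magnitude(state, cfg, direction)

    new_level = state.level + direction * magnitude
    # clamping at a bound does not count as a reversal
    state.level = min(max(new_level, cfg.lower_bound), cfg.upper_bound)
    state.step = magnitude
    state.direction = direction
    state.terminated = pest_terminated(state, cfg)
    return state


def run_staircase(
    cfg: PestConfig,
    respond: Callable[[float], bool],
    start_sign: int,
    max_iter: Optional[int] = None,
) -> PestState:
    """Run a staircase to termination against a responder ``level -> bool``."""
    state = pest_init(cfg, start_sign)
    limit = max_iter if max_iter is not None else cfg.max_trials + 1
    while not state.terminated and state.n_trials < limit:
        pest_update(state, cfg, respond(state.level))
    return state
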