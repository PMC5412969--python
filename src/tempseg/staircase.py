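"""3-down 1-up adaptive staircase with reversal-halved steps.

The staircase makes the task harder (moves the tracked variable *down*)
after three consecutive correct responses and easier (*up*) after any
error, which converges on the (1/2)^(1/3) ~ 79.4% correct performance
level.  The step size starts large (0.215 s for temporal-acuity runs;
the total element count for coherence runs) and halves after every
reversal; the run terminates after 12 reversals and the threshold is the
arithmetic mean of the last six reversal values.  A session estimate is
the mean of at least four staircases.

A *reversal* is a trial at which the direction of value movement changes
(down -> up or up -> down); the value at that trial is logged, and the
step is halved immediately afterwards.  Values are clipped to the
configured bounds without logging a reversal, since clipping is not a
performance-driven direction change.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .observer import ObserverSpec, p_correct

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "StaircaseResult",
    "SessionEstimate",
    "staircase_update",
    "run_staircase",
    "run_session",
    "convergence_probe",
]


@dataclass(frozen=True)
class StaircaseConfig:
    variable: Literal["segment_duration_s", "coherence_units"]
    initial_value: float
    initial_step: float
    lower_bound: float
    upper_bound: float
    n_down: int = 3
    n_up: int = 1
    total_reversals: int = 12
    reversals_averaged: int = 6
    min_staircases_per_estimate: int = 4
    max_trials: int = 10_000

    def __post_init__(self) -> None:
        if self.reversals_averaged > self.total_reversals:
            raise ValueError("reversals_averaged must not exceed total_reversals")
        if not (self.lower_bound < self.upper_bound):
            raise ValueError("bounds must be ordered")
        if not (self.lower_bound <= self.initial_value <= self.upper_bound):
            raise ValueError("initial_value must lie within bounds")
        if self.n_down < 1 or self.n_up != 1:
            raise ValueError("only n-down 1-up rules are supported")


def acuity_config(
    initial_value: float = 0.215,
    initial_step: float = 0.215,
    lower_bound: float = 0.01,
    upper_bound: float = 0.43,
) -> StaircaseConfig:
    """Default temporal-acuity staircase (variable = segment duration, s)."""
    return StaircaseConfig(
        variable="segment_duration_s",
        initial_value=initial_value,
        initial_step=initial_step,
        lower_bound=lower_bound,
        upper_bound=upper_bound,
    )


def coherence_config(
    n_elements: int = 256,
    initial_value: float | None = None,
) -> StaircaseConfig:
    """Default coherence staircase.

    Tracked internally in element units (dots) as reals — the initial step
    equals the total number of elements in the display and halving quickly
    produces fractional values; rounding to integer dot counts happens only
    when a stimulus is actually constructed.
    """
    return StaircaseConfig(
        variable="coherence_units",
        initial_value=float(n_elements) if initial_value is None else initial_value,
        initial_step=float(n_elements),
        lower_bound=0.0,
        upper_bound=float(n_elements),
    )


@dataclass
class StaircaseState:
    current_value: float
    current_step: float
    consecutive_correct: int = 0
    last_move: Literal["down", "up", "none"] = "none"
    reversal_values: list[float] = field(default_factory=list)
    trial_log: list[tuple[float, bool]] = field(default_factory=list)

    def terminated(self, config: StaircaseConfig) -> bool:
        return len(self.reversal_values) >= config.total_reversals


@dataclass(frozen=True)
class StaircaseResult:
    threshold: float
    n_trials: int
    reversal_values: tuple[float, ...]
    converged: bool
    trial_log: tuple[tuple[float, bool], ...]


@dataclass(frozen=True)
class SessionEstimate:
    estimate: float
    per_staircase: tuple[float, ...]
    sd: float
    all_converged: bool


def staircase_update(
    state: StaircaseState, correct: bool, config: StaircaseConfig
) -> StaircaseState:
    """Apply one trial outcome; returns a new state (input left untouched)."""
    if state.terminated(config):
        raise RuntimeError("staircase already terminated")

    value = state.current_value
    step = state.current_step
    consecutive = state.consecutive_correct
    last_move = state.last_move
    reversals = list(state.reversal_values)
    log = list(state.trial_log)
    log.append((value, correct))

    move: str | None = None
    if correct:
        consecutive += 1
        if consecutive >= config.n_down:
            move = "down"
            consecutive = 0
    else:
        move = "up"
        consecutive = 0

    if move is not None:
        if last_move != "none" and move != last_move:
            reversals.append(value)
            step = config.initial_step / 2 ** len(reversals)
        new_value = value - step if move == "down" else value + step
        value = min(max(new_value, config.lower_bound), config.upper_bound)
        last_move = move

    return StaircaseState(
        current_value=value,
        current_step=step,
        consecutive_correct=consecutive,
        last_move=last_move,
        reversal_values=reversals,
        trial_log=log,
    )


def run_staircase(
    config: StaircaseConfig,
    obs: ObserverSpec,
    seed: int | np.random.Generator,
) -> StaircaseResult:
    """Run one staircase against a parametric observer until 12 reversals.

    The threshold is the arithmetic mean of the last ``reversals_averaged``
    reversal values.  Deterministic for a fixed seed.  If the trial cap is
    reached before the reversal quota, the result is flagged non-converged
    and the threshold is computed from whatever reversals accrued (NaN if
    none).

    ``obs`` may be an :class:`ObserverSpec` or any callable mapping a
    stimulus level to a probability of a correct response (the hook for
    stimulus-consuming observers).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    prob = obs if callable(obs) else (lambda level: p_correct(obs, level))
    state = StaircaseState(
        current_value=config.initial_value, current_step=config.initial_step
    )
    while not state.terminated(config) and len(state.trial_log) < config.max_trials:
        correct = bool(rng.random() < prob(state.current_value))
        state = staircase_update(state, correct, config)

    converged = state.terminated(config)
    tail = state.reversal_values[-config.reversals_averaged :]
    threshold = float(np.mean(tail)) if tail else float("nan")
    return StaircaseResult(
        threshold=threshold,
        n_trials=len(state.trial_log),
        reversal_values=tuple(state.reversal_values),
        converged=converged,
        trial_log=tuple(state.trial_log),
    )


def run_session(
    config: StaircaseConfig,
    obs: ObserverSpec,
    n_staircases: int,
    seed: int,
) -> SessionEstimate:
    """Mean threshold over ``n_staircases`` independent staircases (>= 4)."""
    if n_staircases < config.min_staircases_per_estimate:
        raise ValueError(
            f"need at least {config.min_staircases_per_estimate} staircases"
        )
    children = np.random.SeedSequence(seed).spawn(n_staircases)
    results = [run_staircase(config, obs, np.random.default_rng(c)) for c in children]
    thresholds = np.array([r.threshold for r in results])
    return SessionEstimate(
        estimate=float(thresholds.mean()),
        per_staircase=tuple(float(t) for t in thresholds),
        sd=float(thresholds.std(ddof=1)) if n_staircases > 1 else 0.0,
        all_converged=all(r.converged for r in results),
    )


def convergence_probe(n_down: int, n_up: int = 1) -> float:
    """Percent-correct level an n-down/1-up rule tracks: (1/2)^(1/n_down).

    The staircase equilibrates where the probability of n_down consecutive
    correct responses equals 1/2, i.e. p^n_down = 1/2.  For the 3-down
    1-up rule this is 0.7937, displayed as "79%".
    """
    if n_up != 1 or n_down < 1:
        raise ValueError("only n-down 1-up rules are supported")
    return 0.5 ** (1.0 / n_down)
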