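"""Parametric synthetic observers for exercising adaptive staircases.

The observer is a Weibull psychometric function for a two-interval forced
choice (2IFC) task: guessing rate 0.5, optional lapse rate, threshold
location ``alpha`` in the units of the staircased variable (seconds of
segment duration, or percent coherence), and slope ``beta``.  Larger values
of the variable make the task easier for both staircased variables (longer
segments and higher coherence are easier), so the function is monotone
non-decreasing in the level.

This observer is validation plumbing: it lets staircases and whole sessions
be simulated and checked, and makes no claim about human observers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = ["ObserverSpec", "p_correct", "simulate_trial"]


@dataclass(frozen=True)
class ObserverSpec:
    alpha: float
    beta: float
    lapse: float = 0.0
    guess: float = 0.5
    easier_direction: Literal["increasing", "decreasing"] = "increasing"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not (0.0 <= self.lapse <= 0.06):
            raise ValueError("lapse must lie in [0, 0.06]")
        if self.guess != 0.5:
            raise ValueError("guess is fixed at 0.5 for 2IFC")


def p_correct(obs: ObserverSpec, level: float) -> float:
    """Probability of a correct 2IFC response at a stimulus level.

    ``guess + (1 - guess - lapse) * (1 - exp(-(level/alpha)^beta))`` for an
    increasing easier-direction; at level 0 the observer guesses (0.5), and
    the asymptote is ``1 - lapse``.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    x = level / obs.alpha
    if obs.easier_direction == "decreasing":
        x = 0.0 if level == 0 else obs.alpha / level
    p_inner = 1.0 - np.exp(-(x ** obs.beta))
    return float(obs.guess + (1.0 - obs.guess - obs.lapse) * p_inner)


def simulate_trial(
    obs: ObserverSpec, level: float, rng: np.random.Generator
) -> bool:
    """One Bernoulli 2IFC response; reproducible given the generator state."""
    return bool(rng.random() < p_correct(obs, level))
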