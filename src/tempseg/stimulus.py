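"""Temporally segmented random-dot motion and streak-form stimuli.

A stimulus is a short sequence of dot images (default 43 frames at 100 Hz).
In the *motion* task the signal dots translate coherently and the direction
of translation alternates between leftward and rightward in temporal
segments of a given duration; noise dots take a fresh random heading on
every update.  In the *form* task each displayed frame is a static streak
image built by superimposing a short (default 4-frame) motion micro-sequence,
so the signal elements become oriented streaks (vertical or horizontal)
whose orientation alternates between segments.  A *temporally intermingled*
comparison stimulus carries the identical per-frame states in randomized
order, so it contains the same local cues without the block structure.

Coordinates are in degrees of visual angle, origin at the lower-left corner
of the square display window; positions wrap toroidally so dot density is
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "StimulusSpec",
    "SegmentSchedule",
    "DotFrame",
    "FormImage",
    "make_segment_schedule",
    "generate_motion_stimulus",
    "generate_form_stimulus",
    "streak_length",
    "stimulus_summary",
]

STATE_A = "A"
STATE_B = "B"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class StimulusSpec:
    """Geometric and temporal parameters of one dot stimulus.

    Defaults reproduce the standard configuration: 43 images of 256 dots
    at 100 Hz (0.43 s total), 0.035 deg per positional update (3.5 deg/s),
    0.07 deg dots in a 7 x 7 deg window, 22-frame limited lifetime, and a
    0.52 s inter-stimulus interval (metadata only; nothing is rendered
    during the ISI).
    """

    n_dots: int = 256
    n_frames: int = 43
    frame_rate: float = 100.0
    dot_step: float = 0.035
    dot_diameter: float = 0.07
    window_size: float = 7.0
    lifetime_frames: int = 22
    isi: float = 0.52
    coherence: float = 100.0
    segment_duration: float = 0.43
    domain_kind: Literal["motion", "form"] = "motion"
    arrangement: Literal["segmented", "intermingled"] = "segmented"
    form_superposition_frames: int = 4

    def __post_init__(self) -> None:
        if self.n_dots < 1:
            raise ValueError("n_dots must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= self.coherence <= 100.0):
            raise ValueError("coherence must lie in [0, 100]")
        if self.segment_duration < 1.0 / self.frame_rate:
            raise ValueError(
                "segment_duration must be at least one frame period "
                f"({1.0 / self.frame_rate:.4f} s)"
            )
        if self.lifetime_frames > self.n_frames:
            raise ValueError("lifetime_frames must not exceed n_frames")
        if self.domain_kind not in ("motion", "form"):
            raise ValueError(f"unknown domain_kind {self.domain_kind!r}")
        if self.arrangement not in ("segmented", "intermingled"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.form_superposition_frames < 1:
            raise ValueError("form_superposition_frames must be >= 1")

    @property
    def n_signal(self) -> int:
        return _round_half_up(self.coherence / 100.0 * self.n_dots)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SegmentSchedule:
    """Per-frame feature-state labels (A/B) and the segment boundaries.

    For motion, A means leftward and B rightward signal direction; for
    form, A means vertical and B horizontal signal-streak orientation.
    """

    states: tuple[str, ...]
    boundaries: tuple[int, ...]
    arrangement: Literal["segmented", "intermingled"]

    def state_counts(self) -> dict[str, int]:
        return {
            STATE_A: sum(1 for s in self.states if s == STATE_A),
            STATE_B: sum(1 for s in self.states if s == STATE_B),
        }


@dataclass(frozen=True)
class DotFrame:
    """One image of a motion stimulus: dot positions plus bookkeeping."""

    positions: np.ndarray  # (n_dots, 2) degrees
    is_signal: np.ndarray  # (n_dots,) bool
    age: np.ndarray  # (n_dots,) int; meaningful for signal dots
    state: str


@dataclass(frozen=True)
class FormImage:
    """One static streak image built from a superimposed micro-sequence."""

    streak_centers: np.ndarray  # (n_dots, 2) centroid of each element
    is_signal: np.ndarray  # (n_dots,) bool
    streak_orientation: str  # "vertical" | "horizontal" (signal streaks)
    streak_length: float
    state: str


def make_segment_schedule(spec: StimulusSpec, seed: int) -> SegmentSchedule:
    """Build the per-frame state schedule.

    Segmented: boundary of segment ``i`` falls at frame
    ``round(i * segment_duration * frame_rate)`` (half-up), states
    alternating starting from A.  Intermingled: a seeded uniform permutation
    of the matched segmented schedule's per-frame states, so the per-state
    frame counts are identical but the block structure is destroyed.
    """
    n = spec.n_frames
    frames_per_segment = spec.segment_duration * spec.frame_rate
    states = []
    boundaries = []
    i = 0
    start = 0
    while start < n:
        end = min(_round_half_up((i + 1) * frames_per_segment), n)
        if end <= start:  # guard against pathological rounding stalls
            end = start + 1
        state = STATE_A if i % 2 == 0 else STATE_B
        states.extend([state] * (end - start))
        if end < n:
            boundaries.append(end)
        start = end
        i += 1

    if spec.arrangement == "intermingled":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        states = [states[j] for j in perm]
        boundaries = [
            j for j in range(1, n) if states[j] != states[j - 1]
        ]

    return SegmentSchedule(
        states=tuple(states),
        boundaries=tuple(boundaries),
        arrangement=spec.arrangement,
    )


def _unit_step(state: str, domain: str) -> np.ndarray:
    """Signal displacement direction for a schedule state.

    Motion: A = leftward (-x), B = rightward (+x).  Form micro-sequences:
    A = vertical axis (+y), B = horizontal axis (+x).
    """
    if domain == "motion":
        return np.array([-1.0, 0.0]) if state == STATE_A else np.array([1.0, 0.0])
    return np.array([0.0, 1.0]) if state == STATE_A else np.array([1.0, 0.0])


def generate_motion_stimulus(
    spec: StimulusSpec, schedule: SegmentSchedule, seed: int
) -> list[DotFrame]:
    """Simulate the dot trajectories of one motion stimulus.

    Signal dots step ``dot_step`` in the scheduled direction on every
    update; noise dots step ``dot_step`` in an independent uniformly random
    direction.  Each signal dot carries an age initialized uniformly in
    1..lifetime_frames; when the age exceeds the lifetime the dot is
    replotted at a uniformly random location with age reset to 1.
    Positions wrap toroidally.  Bit-identical for a fixed seed.
    """
    if spec.domain_kind != "motion":
        raise ValueError("spec.domain_kind must be 'motion'")
    if len(schedule.states) != spec.n_frames:
        raise ValueError("schedule does not cover n_frames")

    rng = np.random.default_rng(seed)
    w = spec.window_size
    n = spec.n_dots
    n_sig = spec.n_signal

    pos = rng.uniform(0.0, w, size=(n, 2))
    is_signal = np.zeros(n, dtype=bool)
    is_signal[rng.choice(n, size=n_sig, replace=False)] = True
    age = np.zeros(n, dtype=int)
    age[is_signal] = rng.integers(1, spec.lifetime_frames + 1, size=n_sig)

    frames = [
        DotFrame(pos.copy(), is_signal.copy(), age.copy(), schedule.states[0])
    ]
    for u in range(1, spec.n_frames):
        state = schedule.states[u]
        step = _unit_step(state, "motion") * spec.dot_step
        pos[is_signal] += step
        n_noise = n - n_sig
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n_noise)
        pos[~is_signal] += spec.dot_step * np.column_stack(
            (np.cos(theta), np.sin(theta))
        )
        pos %= w
        age[is_signal] += 1
        expired = is_signal & (age > spec.lifetime_frames)
        k = int(expired.sum())
        if k:
            pos[expired] = rng.uniform(0.0, w, size=(k, 2))
            age[expired] = 1
        frames.append(
            DotFrame(pos.copy(), is_signal.copy(), age.copy(), state)
        )
    return frames


def streak_length(spec: StimulusSpec) -> float:
    """Spatial extent of a signal streak in the form task, in degrees.

    A streak is a dot of diameter ``dot_diameter`` dragged through
    ``form_superposition_frames - 1`` updates of ``dot_step`` each:
    0.07 + 3 x 0.035 = 0.175 deg, displayed as 0.18 with half-up rounding.
    """
    return spec.dot_diameter + (spec.form_superposition_frames - 1) * spec.dot_step


def streak_length_display(spec: StimulusSpec) -> float:
    """streak_length rounded half-up to two decimals (display convention)."""
    return _round_half_up(streak_length(spec) * 100.0) / 100.0


def generate_form_stimulus(
    spec: StimulusSpec, schedule: SegmentSchedule, seed: int
) -> list[FormImage]:
    """Simulate one streak-form stimulus.

    Every displayed frame is a fresh static image obtained by superimposing
    a ``form_superposition_frames``-frame motion micro-sequence whose signal
    dots move along the scheduled axis (A = vertical, B = horizontal) while
    noise dots move randomly, so signal elements form common-axis streaks
    and noise elements form random clusters.  Images are regenerated on
    every frame for both arrangements, equating update statistics between
    the test and comparison stimuli.
    """
    if spec.domain_kind != "form":
        raise ValueError("spec.domain_kind must be 'form'")
    if len(schedule.states) != spec.n_frames:
        raise ValueError("schedule does not cover n_frames")

    rng = np.random.default_rng(seed)
    w = spec.window_size
    n = spec.n_dots
    n_sig = spec.n_signal
    m = spec.form_superposition_frames
    length = streak_length(spec)

    images: list[FormImage] = []
    for u in range(spec.n_frames):
        state = schedule.states[u]
        axis = _unit_step(state, "form") * spec.dot_step
        pos = rng.uniform(0.0, w, size=(n, 2))
        is_signal = np.zeros(n, dtype=bool)
        is_signal[rng.choice(n, size=n_sig, replace=False)] = True
        traj = np.empty((m, n, 2))
        traj[0] = pos
        for f in range(1, m):
            pos = pos.copy()
            pos[is_signal] += axis
            n_noise = n - n_sig
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n_noise)
            pos[~is_signal] += spec.dot_step * np.column_stack(
                (np.cos(theta), np.sin(theta))
            )
            pos %= w
            traj[f] = pos
        centers = traj.mean(axis=0)
        images.append(
            FormImage(
                streak_centers=centers,
                is_signal=is_signal,
                streak_orientation="vertical" if state == STATE_A else "horizontal",
                streak_length=length,
                state=state,
            )
        )
    return images


def stimulus_summary(
    frames: Sequence[DotFrame | FormImage], spec: StimulusSpec
) -> dict:
    """Summary record: realized coherence, duration, state counts, signal step.

    For motion frames the mean per-update signal displacement is measured
    from the trajectories (lifetime replot updates excluded); for form
    images it is the micro-sequence step, i.e. ``dot_step`` by construction.
    """
    if len(frames) == 0:
        raise ValueError("empty stimulus")
    n_sig = int(np.sum(frames[0].is_signal))
    counts: dict[str, int] = {STATE_A: 0, STATE_B: 0}
    for f in frames:
        counts[f.state] += 1

    if isinstance(frames[0], DotFrame):
        disps = []
        for prev, cur in zip(frames[:-1], frames[1:]):
            sig = prev.is_signal
            replot = cur.age[sig] == 1
            d = cur.positions[sig] - prev.positions[sig]
            # undo toroidal wrap for the displacement measurement
            d = (d + spec.window_size / 2) % spec.window_size - spec.window_size / 2
            mags = np.linalg.norm(d, axis=1)[~replot]
            disps.extend(mags.tolist())
        mean_step = float(np.mean(disps)) if disps else float("nan")
    else:
        mean_step = spec.dot_step

    return {
        "realized_coherence_pct": 100.0 * n_sig / spec.n_dots,
        "n_signal": n_sig,
        "duration_s": len(frames) / spec.frame_rate,
        "state_frame_counts": counts,
        "mean_signal_step_deg": mean_step,
        "signal_speed_deg_per_s": spec.dot_step * spec.frame_rate,
    }


def export_motion_csv(frames: Sequence[DotFrame], path) -> None:
    """Tidy CSV export: frame, dot_id, x_deg, y_deg, is_signal, state."""
    import pandas as pd

    rows = []
    for f_idx, f in enumerate(frames):
        n = f.positions.shape[0]
        rows.append(
            {
                "frame": np.full(n, f_idx),
                "dot_id": np.arange(n),
                "x_deg": f.positions[:, 0],
                "y_deg": f.positions[:, 1],
                "is_signal": f.is_signal.astype(int),
                "state": np.full(n, f.state),
            }
        )
    df = pd.concat([pd.DataFrame(r) for r in rows], ignore_index=True)
    df.to_csv(path, index=False)
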