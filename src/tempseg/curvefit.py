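"""Two-limbed threshold-versus-segment-duration curve and its fit.

Coherence thresholds fall as segment duration grows, up to a knee-point
beyond which performance no longer improves.  The curve is the standard
log-log broken stick with a flat upper limb:

    y(x) = t * (k / x)^s   for x <  k        (descending limb)
    y(x) = t               for x >= k        (asymptote)

with knee-point ``k`` (seconds), asymptotic threshold ``t`` (percent
coherence) and descending-limb slope ``s`` (log-log units, >= 0).  The
curve is continuous at the knee and monotone non-increasing in x.
Equivalently log10 y = log10 t + s * log10(k/x) * (sgn(log10(k/x)) + 1)/2.

Fitting minimizes squared residuals of log10 threshold against
log10-duration predictions (thresholds are ratio-scaled and the limb is
linear in log-log), using bounded least squares with multi-start
initialization over candidate knee locations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ThresholdCurve",
    "TwoLimbedFit",
    "default_duration_grid",
    "two_limbed",
    "fit_two_limbed",
    "r_squared",
]


def default_duration_grid(n_points: int = 5) -> np.ndarray:
    """Segment-duration grid: 0.03 to 0.215 s in equal log10 steps."""
    return np.logspace(np.log10(0.03), np.log10(0.215), n_points)


@dataclass(frozen=True)
class ThresholdCurve:
    durations: np.ndarray  # seconds, strictly increasing
    thresholds: np.ndarray  # percent coherence, (0, 100]
    task: Literal["motion", "form"] = "motion"

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=float)
        y = np.asarray(self.thresholds, dtype=float)
        object.__setattr__(self, "durations", d)
        object.__setattr__(self, "thresholds", y)
        if d.ndim != 1 or y.shape != d.shape:
            raise ValueError("durations and thresholds must be equal-length 1-D")
        if np.any(np.diff(d) <= 0) or np.any(d <= 0):
            raise ValueError("durations must be strictly increasing and positive")
        if np.any(y <= 0) or np.any(y > 100):
            raise ValueError("thresholds must lie in (0, 100]")


@dataclass(frozen=True)
class TwoLimbedFit:
    k: float
    t: float
    s: float
    r_squared: float
    converged: bool
    residuals: np.ndarray  # log10 scale


def two_limbed(x, k: float, t: float, s: float):
    """Evaluate the two-limbed curve; scalar or array ``x``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or k <= 0 or t <= 0:
        raise ValueError("x, k and t must be positive")
    if s < 0:
        raise ValueError("s must be >= 0")
    y = np.where(x < k, t * (k / x) ** s, t)
    return float(y) if y.ndim == 0 else y


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot, on the given scale.

    Zero total variance with (numerically) zero residuals is a perfect fit
    of flat data and returns 1.0; zero total variance with nonzero
    residuals is undefined and returns NaN.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed/predicted must be equal length >= 2")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-20 else float("nan")
    return 1.0 - ss_res / ss_tot


def _log_residuals(params: np.ndarray, log_x: np.ndarray, log_y: np.ndarray):
    log_k, log_t, s = params
    excess = log_k - log_x  # log10(k/x)
    pred = log_t + s * np.clip(excess, 0.0, None)
    return pred - log_y


def fit_two_limbed(curve: ThresholdCurve) -> TwoLimbedFit:
    """Least-squares fit of (k, t, s) on the log10-log10 scale.

    Multi-start: the knee is initialized at every interior grid duration,
    the asymptote at the minimum observed threshold, and the slope from
    the first-to-last point slope (clipped to bounds); the best objective
    wins, ties broken by smallest k.  Bounds: k in
    [min duration / 2, max duration * 2], t in (0, 100], s in [0, 10].
    """
    x = curve.durations
    y = curve.thresholds
    if x.size < 4:
        raise ValueError("need at least 4 data points to fit 3 parameters")

    log_x = np.log10(x)
    log_y = np.log10(y)

    lo = np.array([np.log10(x[0] / 2.0), np.log10(1e-6), 0.0])
    hi = np.array([np.log10(x[-1] * 2.0), np.log10(100.0), 10.0])

    t0 = np.clip(np.log10(y.min()), lo[1], hi[1])
    s_end = (log_y[0] - log_y[-1]) / (log_x[-1] - log_x[0])
    s0 = float(np.clip(s_end, 0.0, 10.0))
    k_starts = list(log_x[1:-1]) or [np.log10(np.sqrt(x[0] * x[-1]))]
    k_starts += [lo[0], hi[0]]

    best: tuple[float, float, np.ndarray] | None = None  # (cost, k, params)
    success = False
    for log_k0 in k_starts:
        p0 = np.clip(np.array([log_k0, t0, s0]), lo, hi)
        try:
            sol = least_squares(
                _log_residuals,
                p0,
                bounds=(lo, hi),
                args=(log_x, log_y),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        success = success or sol.success
        cost = float(np.sum(sol.fun**2))
        k_val = 10.0 ** sol.x[0]
        cand = (cost, k_val, sol.x)
        if (
            best is None
            or cost < best[0] - 1e-14
            or (abs(cost - best[0]) <= 1e-14 and k_val < best[1])
        ):
            best = cand

    assert best is not None
    _, _, p = best
    k, t, s = 10.0 ** p[0], 10.0 ** p[1], float(p[2])
    resid = _log_residuals(p, log_x, log_y)
    # r2 on the fitting scale: predicted = observed + residual
    r2 = r_squared(log_y, log_y + resid)
    return TwoLimbedFit(
        k=k, t=t, s=s, r_squared=r2, converged=bool(success), residuals=resid
    )


def grid_search_oracle(
    curve: ThresholdCurve,
    n_grid: int = 100,
) -> tuple[float, tuple[float, float, float]]:
    """Dense brute-force search over (k, t, s); independent check of the fit.

    Returns the best sum of squared log10 residuals and its parameters.
    Intended for tests, not production fitting.
    """
    x, y = curve.durations, curve.thresholds
    log_x, log_y = np.log10(x), np.log10(y)
    ks = np.logspace(np.log10(x[0] / 2.0), np.log10(x[-1] * 2.0), n_grid)
    ts = np.logspace(np.log10(y.min() / 3.0), np.log10(min(y.max() * 3.0, 100.0)), n_grid)
    ss = np.linspace(0.0, 10.0, n_grid)
    excess = np.clip(np.log10(ks)[:, None] - log_x[None, :], 0.0, None)  # (k, x)
    pred = (
        np.log10(ts)[None, :, None, None]
        + ss[None, None, :, None] * excess[:, None, None, :]
    )  # (k, t, s, x)
    sse = np.sum((pred - log_y[None, None, None, :]) ** 2, axis=-1)
    idx = np.unravel_index(np.argmin(sse), sse.shape)
    return float(sse[idx]), (float(ks[idx[0]]), float(ts[idx[1]]), float(ss[idx[2]]))
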