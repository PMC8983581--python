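"""FRAP trace normalization and single-exponential recovery fitting.

The recovery of a photobleached region is modelled with the canonical
simple-exponential form

    I(t) = I0 + A · (1 − 2^(−t / T_1/2)),

where I0 is the post-bleach floor, A the fitted plateau rise and T_1/2 the
half-time of recovery: I(T_1/2) − I0 = A/2 by construction.  The mobile
fraction is M_f = A / (1 − I0), the recovered share of the bleached signal
on the double-normalized scale where the pre-bleach level is 1.

Traces are normalized by background subtraction and division by an
unbleached reference (which cancels acquisition photobleaching drift),
then rescaled so that the pre-bleach level maps to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import NormalizationError

logger = logging.getLogger(__name__)

__all__ = ["FrapTrace", "FrapFit", "recovery_model", "normalize_trace",
           "fit_recovery", "group_mean_sd"]


@dataclass
class FrapTrace:
    """Raw FRAP time series; bleach at t = 0, time strictly increasing.

    ``background`` and ``reference`` may be scalars or per-point arrays;
    ``prebleach`` is the pre-bleach ROI intensity (a.u.).
    """

    time: np.ndarray         # s
    roi: np.ndarray          # a.u.
    background: np.ndarray   # a.u.
    reference: np.ndarray    # a.u., unbleached punctum/condensate
    prebleach: float         # a.u.

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.roi = np.asarray(self.roi, float)
        self.background = np.broadcast_to(
            np.asarray(self.background, float), self.time.shape).copy()
        self.reference = np.broadcast_to(
            np.asarray(self.reference, float), self.time.shape).copy()
        if not (self.time.shape == self.roi.shape):
            raise ValueError("time and roi must have equal lengths")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class FrapFit:
    t_half: float            # s
    m_f: float               # mobile fraction
    floor: float             # fitted post-bleach floor (normalized units)
    rss: float               # residual sum of squares
    converged: bool
    message: str = ""


def recovery_model(t, floor, amplitude, t_half):
    """I(t) = floor + amplitude · (1 − 2^(−t/t_half))."""
    return floor + amplitude * (1.0 - 2.0 ** (-t / t_half))


def normalize_trace(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract, divide by the reference, rescale pre-bleach to 1.

    Returns ``(time, values)`` with the pre-bleach level at 1 and the first
    post-bleach point at its bleached fraction.  Raises
    :class:`NormalizationError` if the reference does not stay above
    background.
    """
    denom = trace.reference - trace.background
    if np.any(denom <= 0):
        raise NormalizationError("reference does not exceed background at all points")
    values = (trace.roi - trace.background) / denom
    pre = (trace.prebleach - trace.background[0]) / denom[0]
    if pre <= 0:
        raise NormalizationError("pre-bleach intensity does not exceed background")
    return trace.time, values / pre


def fit_recovery(
    time: np.ndarray,
    values: np.ndarray,
    min_points: int = 8,
    mf_cap: float = 1.05,
    fix_floor: float | None = None,
) -> FrapFit:
    """Least-squares fit of the single-exponential recovery.

    Needs at least ``min_points`` post-bleach points.  The fit reports
    ``converged=False`` (with diagnostics, never a silent fallback) when the
    optimizer fails, the amplitude collapses to ~0 (immobile trace), or the
    mobile fraction leaves (0, ``mf_cap``].

    ``fix_floor`` pins the post-bleach floor instead of fitting it — the
    full-scale normalization convention, where the first post-bleach level
    is taken as known (e.g. 0 after a complete bleach).  Removing the floor
    parameter tightens the half-time estimate appreciably at realistic
    noise; use it whenever the bleach depth is set by the protocol.
    """
    time = np.asarray(time, float)
    values = np.asarray(values, float)
    if time.size < min_points:
        raise ValueError(f"need >= {min_points} post-bleach points, got {time.size}")

    floor0 = float(values[0])
    tail = values[max(1, int(0.8 * values.size)):]
    plateau0 = float(tail.mean())
    amp0 = max(plateau0 - floor0, 1e-3)
    # initial rate from a log-linear fit of the residual decay
    resid = plateau0 - values
    ok = resid > 1e-4 * max(amp0, 1e-12)
    if ok.sum() >= 3:
        slope = np.polyfit(time[ok], np.log(resid[ok]), 1)[0]
        th0 = np.log(2) / max(-slope, 1e-9) if slope < 0 else time[-1] / 4
    else:
        th0 = time[-1] / 4
    th0 = float(np.clip(th0, time[1] - time[0] if time.size > 1 else 1e-3, 10 * time[-1]))

    try:
        if fix_floor is None:
            bounds = ([-0.5, 0.0, 1e-9], [1.1, 1.5, 10.0 * time[-1]])
            p0 = [np.clip(floor0, -0.5, 1.1), np.clip(amp0, 0, 1.5), th0]
            popt, _ = curve_fit(recovery_model, time, values, p0=p0,
                                bounds=bounds, maxfev=20000)
        else:
            def model2(t, amplitude, t_half):
                return recovery_model(t, fix_floor, amplitude, t_half)
            bounds = ([0.0, 1e-9], [1.5, 10.0 * time[-1]])
            amp0 = max(plateau0 - fix_floor, 1e-3)
            p0 = [np.clip(amp0, 0, 1.5), th0]
            popt2, _ = curve_fit(model2, time, values, p0=p0,
                                 bounds=bounds, maxfev=20000)
            popt = np.array([fix_floor, popt2[0], popt2[1]])
    except (RuntimeError, ValueError) as exc:
        return FrapFit(t_half=float("nan"), m_f=float("nan"), floor=float("nan"),
                       rss=float("nan"), converged=False,
                       message=f"optimizer failed: {exc}")
    floor, amp, t_half = (float(v) for v in popt)
    rss = float(np.sum((recovery_model(time, *popt) - values) ** 2))
    m_f = amp / (1.0 - floor) if floor < 1.0 else float("inf")

    converged, message = True, ""
    if amp < 1e-3:
        converged, message = False, "amplitude at zero boundary (immobile trace)"
    elif not (0.0 < m_f <= mf_cap):
        converged, message = False, f"mobile fraction {m_f:.3g} outside (0, {mf_cap}]"
    elif t_half >= 9.99 * time[-1]:
        converged, message = False, "half-time at upper bound (no recovery observed)"
    return FrapFit(t_half=t_half, m_f=m_f, floor=floor, rss=rss,
                   converged=converged, message=message)


def fit_trace(trace: FrapTrace, **kwargs) -> FrapFit:
    """Normalize then fit a raw trace; convenience wrapper."""
    return fit_recovery(*normalize_trace(trace), **kwargs)


def group_mean_sd(traces: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean ± SD recovery over traces sharing a common time grid."""
    if not traces:
        raise ValueError("no traces")
    t0 = np.asarray(traces[0][0])
    vals = []
    for t, v in traces:
        if not np.allclose(t, t0):
            raise ValueError("traces must share a common time grid")
        vals.append(np.asarray(v))
    arr = np.stack(vals)
    return t0, arr.mean(axis=0), arr.std(axis=0, ddof=1)
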