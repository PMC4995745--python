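"""Quantification of oscillatory responses.

Amplitude is measured peak-to-trough over the settled part of a
trajectory (robust against baseline shifts), the period as the mean
spacing of successive refined peaks, and a response counts as sustained
when the cycle amplitude stops decaying.  Pulse shape is summarized by
the mean time per cycle above/below a threshold ("On"/"Off" states).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .dde import Trajectory, simulate
from .models import ModelParams, ModelSpec

__all__ = [
    "OscillationMetrics",
    "PulseDurations",
    "measure_oscillation",
    "amplitude_period_curve",
    "on_off_durations",
    "NotOscillatoryError",
]


class NotOscillatoryError(RuntimeError):
    pass


@dataclass(frozen=True)
class OscillationMetrics:
    """Summary of the settled oscillation of one observable."""

    amplitude: float
    period: float  # NaN when fewer than 2 peaks
    sustained: bool
    n_peaks_used: int
    decay_ratio: float = np.nan  # last-cycle / first-cycle amplitude in the window


@dataclass(frozen=True)
class PulseDurations:
    """Mean per-cycle time above (On) and below (Off) a threshold."""

    on_duration: float
    off_duration: float
    threshold: float


def _series(traj: Trajectory, observable: str) -> np.ndarray:
    if observable not in ("C", "R"):
        raise ValueError("observable must be 'C' or 'R'")
    return traj.C if observable == "C" else traj.R


def _refine(t: np.ndarray, x: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic (3-point parabola) refinement of discrete extrema."""
    times, values = [], []
    for i in idx:
        if i == 0 or i == len(t) - 1:
            times.append(t[i]); values.append(x[i])
            continue
        t0, t1, t2 = t[i - 1], t[i], t[i + 1]
        y0, y1, y2 = x[i - 1], x[i], x[i + 1]
        denom = (y0 - 2 * y1 + y2)
        if denom == 0:
            times.append(t1); values.append(y1)
            continue
        h = t1 - t0  # uniform grid assumed for the refinement step
        shift = 0.5 * (y0 - y2) / denom * h
        times.append(t1 + shift)
        values.append(y1 - 0.25 * (y0 - y2) * shift / h)
    return np.asarray(times), np.asarray(values)


def measure_oscillation(
    traj: Trajectory,
    observable: str = "C",
    settle_fraction: float = 0.5,
) -> OscillationMetrics:
    """Amplitude/period/sustainedness of the post-transient oscillation.

    The first ``settle_fraction`` of the trajectory is discarded as
    transient.  Monotone or flat responses return amplitude 0 and
    ``sustained=False``.
    """
    if not 0 <= settle_fraction < 1:
        raise ValueError("settle_fraction must be in [0, 1)")
    x_full = _series(traj, observable)
    mask = traj.t >= settle_fraction * traj.t[-1]
    t, x = traj.t[mask], x_full[mask]
    scale = max(np.max(np.abs(x_full)), 1e-300)
    prom = 1e-6 * scale  # ignore solver-level ripple
    peaks, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    if len(peaks) == 0 or len(troughs) == 0:
        return OscillationMetrics(0.0, np.nan, False, 0)

    pk_t, pk_v = _refine(t, x, peaks)
    tr_t, tr_v = _refine(t, x, troughs)
    amplitude = float(np.mean(pk_v) - np.mean(tr_v))
    period = float(np.mean(np.diff(pk_t))) if len(pk_t) >= 2 else np.nan

    # per-cycle amplitude: peak minus the following trough
    cyc_amp = []
    for ti, vi in zip(pk_t, pk_v):
        after = tr_v[tr_t > ti]
        if len(after):
            cyc_amp.append(vi - after[0])
    sustained = False
    decay = np.nan
    if len(cyc_amp) >= 2:
        decay = float(cyc_amp[-1] / cyc_amp[0]) if cyc_amp[0] > 0 else np.nan
        rel_change = abs(cyc_amp[-1] - cyc_amp[-2]) / max(cyc_amp[-1], 1e-300)
        sustained = (
            len(pk_t) >= 3 and rel_change < 0.01 and cyc_amp[-1] > 1e-6 * scale
        )
    return OscillationMetrics(
        amplitude=amplitude, period=period, sustained=bool(sustained),
        n_peaks_used=int(len(pk_t)), decay_ratio=decay,
    )


def _curve_t_end(params: ModelParams) -> float:
    # long enough for >= 5 settled peaks: period grows roughly linearly with tau
    return max(40.0 * params.tau, 60.0 / params.beta + 25.0 * params.tau)


def amplitude_period_curve(
    spec: ModelSpec,
    params: ModelParams,
    tau_grid: Iterable[float],
    observable: str = "C",
    t_end: Optional[float] = None,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> pd.DataFrame:
    """Amplitude and period of the settled response for each delay in the grid.

    One simulation + measurement per tau; the horizon auto-extends (up to
    two doublings) until at least 5 post-transient peaks are available.
    """
    rows = []
    for tau in tau_grid:
        if tau <= 0:
            raise ValueError("tau_grid entries must be > 0")
        p = params.with_value("tau", float(tau))
        horizon = t_end if t_end is not None else _curve_t_end(p)
        for _ in range(3):
            traj = simulate(spec, p, t_end=horizon, rel_tol=rel_tol, abs_tol=abs_tol,
                            n_grid=max(2001, int(40 * horizon)))
            m = measure_oscillation(traj, observable)
            if m.n_peaks_used >= 5 or not m.sustained:
                break
            horizon *= 2
        rows.append({
            "tau": float(tau), "amplitude": m.amplitude, "period": m.period,
            "sustained": m.sustained, "n_peaks": m.n_peaks_used,
        })
    return pd.DataFrame(rows)


def on_off_durations(
    traj: Trajectory,
    observable: str = "C",
    threshold_rule: str = "midrange",
    threshold: Optional[float] = None,
    settle_fraction: float = 0.5,
) -> PulseDurations:
    """Mean On/Off durations per cycle of a sustained oscillation.

    The threshold defaults to the midrange (max+min)/2 of the settled
    oscillation; crossings are located by linear interpolation and only
    complete cycles (up-crossing to up-crossing) are averaged.
    """
    if threshold_rule not in ("midrange", "absolute"):
        raise ValueError("threshold_rule must be 'midrange' or 'absolute'")
    if threshold_rule == "absolute" and threshold is None:
        raise ValueError("threshold_rule='absolute' requires a threshold value")
    x_full = _series(traj, observable)
    mask = traj.t >= settle_fraction * traj.t[-1]
    t, x = traj.t[mask], x_full[mask]
    thr = threshold if threshold_rule == "absolute" else 0.5 * (x.max() + x.min())

    s = x - thr
    sign = np.sign(s)
    # crossing between samples i and i+1, linearly interpolated
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if len(idx) < 3:
        raise NotOscillatoryError(
            "fewer than 2 threshold cycles found; check measure_oscillation first"
        )
    t_cross = t[idx] + (t[idx + 1] - t[idx]) * (-s[idx]) / (s[idx + 1] - s[idx])
    up = s[idx] < 0  # crossing upward

    up_times = t_cross[up]
    if len(up_times) < 2:
        raise NotOscillatoryError("fewer than 2 upward crossings")
    # restrict to complete cycles between first and last up-crossing
    in_cycle = (t_cross >= up_times[0]) & (t_cross <= up_times[-1])
    tc, isup = t_cross[in_cycle], up[in_cycle]
    on = off = 0.0
    for a, b, a_up in zip(tc[:-1], tc[1:], isup[:-1]):
        if a_up:
            on += b - a
        else:
            off += b - a
    n_cycles = len(up_times) - 1
    return PulseDurations(
        on_duration=float(on / n_cycles),
        off_duration=float(off / n_cycles),
        threshold=float(thr),
    )
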