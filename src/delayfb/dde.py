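"""Forward integration of the delay models by the method of steps.

On each interval [k*tau, (k+1)*tau] the delayed term C(t - tau) is a
known function (the history for k = 0, the previous segment's dense
interpolant otherwise), which reduces the DDE to an ordinary ODE solved
with a stiff-capable integrator.  For tau = 0 the system is a plain ODE
and is integrated in one call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .models import ModelParams, ModelSpec, validate_pair

__all__ = ["HistorySpec", "Trajectory", "simulate", "default_t_end", "IntegrationError"]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class HistorySpec:
    """Initial history on [-tau, 0].

    ``kind="constant"`` holds (C0, R0) over the whole history interval;
    ``kind="function"`` samples ``func(t) -> (C, R)`` for t in [-tau, 0].
    The default (0, 0) represents an unstimulated system switched on at
    t = 0.
    """

    kind: str = "constant"
    C0: float = 0.0
    R0: float = 0.0
    func: Optional[Callable[[float], tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "function"):
            raise ValueError(f"unknown history kind {self.kind!r}")
        if self.kind == "function" and self.func is None:
            raise ValueError("kind='function' requires func")
        if self.kind == "constant" and (self.C0 < 0 or self.R0 < 0):
            raise ValueError("history values must be >= 0")

    def value(self, t: float) -> tuple[float, float]:
        if self.kind == "constant":
            return (self.C0, self.R0)
        return self.func(t)

    def validate(self, spec: ModelSpec) -> None:
        if spec.mass_conservation and self.kind == "constant" and self.C0 > 1:
            raise ValueError("history C0 must lie in [0, 1] under mass conservation")


@dataclass
class Trajectory:
    """Simulated path sampled on a strictly increasing time grid."""

    t: np.ndarray
    C: np.ndarray
    R: np.ndarray
    meta: dict = field(default_factory=dict)
    _segments: list = field(default_factory=list, repr=False)
    _history: Optional[HistorySpec] = field(default=None, repr=False)

    def __call__(self, ts) -> np.ndarray:
        """Evaluate (C, R) at arbitrary times via the stored dense output."""
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        out = np.empty((2, ts.size))
        for i, t in enumerate(ts):
            out[:, i] = self._eval_one(t)
        return out

    def _eval_one(self, t: float) -> np.ndarray:
        if t <= 0:
            if self._history is None:
                raise ValueError("no history stored for t <= 0")
            return np.asarray(self._history.value(t), dtype=float)
        for t0, t1, sol in self._segments:
            if t <= t1 or t1 == self._segments[-1][1]:
                return sol(min(max(t, t0), t1))
        raise ValueError(f"time {t} outside the simulated range")


def default_t_end(params: ModelParams) -> float:
    """Horizon long enough to leave a settled post-transient window."""
    return max(50.0 * params.tau, 200.0 / params.beta)


def _fast_rhs(spec: ModelSpec, params: ModelParams):
    """Closure evaluating the model right-hand side on raw floats.

    Negative excursions of the solver iterates are clamped to 0 inside
    the Hill nonlinearities (real powers require non-negative bases).
    """
    fb = params.feedback
    I, alpha, beta, delta = params.I, params.alpha, params.beta, params.delta
    n, K_m, nu, kappa = fb.n, fb.K_m, fb.nu, fb.kappa
    input_inh = spec.dnf_mechanism == "input_inhibition"
    mass = spec.mass_conservation

    def f(t, y, delayed_C):
        C = y[0] if y[0] > 0.0 else 0.0
        R = y[1] if y[1] > 0.0 else 0.0
        F = 1.0 / (1.0 + (kappa * C) ** nu) if kappa > 0.0 else 1.0
        ratio = (R / K_m) ** n
        if input_inh:
            prod = I * F / (1.0 + ratio)
            lossC = alpha * C
        else:
            prod = I * F
            lossC = alpha * C + delta * C * ratio / (1.0 + ratio)
        if mass:
            prod *= 1.0 - C
        dC = prod - lossC
        dR = delayed_C(t) - beta * y[1]
        return (dC, dR)

    return f


def simulate(
    spec: ModelSpec,
    params: ModelParams,
    history: Optional[HistorySpec] = None,
    t_end: Optional[float] = None,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    max_step: float = np.inf,
    n_grid: int = 2001,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from its history up to ``t_end``.

    Returns a Trajectory sampled on a uniform grid of ``n_grid`` points;
    the object is also callable for exact dense-output evaluation at
    arbitrary times (used by the fitting stage).
    """
    validate_pair(spec, params)
    history = history or HistorySpec()
    history.validate(spec)
    if t_end is None:
        t_end = default_t_end(params)
    if t_end <= 0 or rel_tol <= 0 or abs_tol <= 0:
        raise ValueError("t_end and tolerances must be > 0")

    f = _fast_rhs(spec, params)
    tau = params.tau
    y0 = np.asarray(history.value(0.0), dtype=float)
    segments: list[tuple[float, float, Callable]] = []

    if tau == 0.0:
        def delayed(t, _seg=None):
            raise AssertionError  # replaced below
        def f0(t, y):
            return f(t, y, lambda _t: (y[0] if y[0] > 0.0 else 0.0))
        sol = solve_ivp(f0, (0.0, t_end), y0, method=method, rtol=rel_tol,
                        atol=abs_tol, max_step=max_step, dense_output=True)
        if not sol.success:
            raise IntegrationError(f"integration failed at t={sol.t[-1]}: {sol.message}")
        segments.append((0.0, t_end, sol.sol))
    else:
        n_seg = math.ceil(t_end / tau - 1e-12)
        prev_sol = None
        for k in range(n_seg):
            t0, t1 = k * tau, min((k + 1) * tau, t_end)
            if k == 0:
                def delayed_C(t, _h=history, _tau=tau):
                    v = _h.value(t - _tau)[0]
                    return v if v > 0.0 else 0.0
            else:
                def delayed_C(t, _s=prev_sol, _tau=tau, _a=t0 - tau, _b=t0):
                    v = _s(min(max(t - _tau, _a), _b))[0]
                    return v if v > 0.0 else 0.0
            sol = solve_ivp(
                f, (t0, t1), y0, args=(delayed_C,), method=method,
                rtol=rel_tol, atol=abs_tol, max_step=max_step, dense_output=True,
            )
            if not sol.success or not np.all(np.isfinite(sol.y)):
                raise IntegrationError(
                    f"integration failed on [{t0}, {t1}]: {sol.message}"
                )
            segments.append((t0, t1, sol.sol))
            prev_sol = sol.sol
            y0 = sol.y[:, -1]

    traj = Trajectory(
        t=np.array([]), C=np.array([]), R=np.array([]),
        meta={
            "model_id": spec.model_id, "params": params.to_dict(),
            "t_end": float(t_end), "rel_tol": rel_tol, "abs_tol": abs_tol,
            "method": method,
        },
        _segments=segments, _history=history,
    )
    grid = np.linspace(0.0, t_end, n_grid)
    vals = traj(grid)
    traj.t, traj.C, traj.R = grid, vals[0], vals[1]
    if traj.C.min() < -1e-8 or traj.R.min() < -1e-8:
        raise IntegrationError("trajectory left the non-negative orthant")
    return traj
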