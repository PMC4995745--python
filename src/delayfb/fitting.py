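"""Least-squares parameter estimation for the delay models.

The objective is the sum of squared residuals between the simulated
observable (C by default) and observed time points,

    SSR(p) = sum_i (x(t_i, p) - x_i)^2.

Optimization runs Nelder-Mead first and restarts with differential
evolution (a global stochastic search) when the simplex stagnates
without converging; convergence requires both the objective decrease and
the parameter-step size between successive bests to fall below 1e-8.

Robustness of a fitted solution is summarized by the coefficient of
variation of the integral of the first transient response (from t = 0 to
the first minimum after the first maximum) under uniform +/- 10%
perturbation of all fitted parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import OptimizeResult, differential_evolution, minimize
from scipy.signal import argrelextrema

from .dde import HistorySpec, IntegrationError, Trajectory, simulate
from .models import ModelParams, ModelSpec

__all__ = [
    "TimeSeriesData",
    "FitResult",
    "ssr",
    "fit",
    "first_transient_integral",
    "robustness",
    "CONVERGENCE_TOL",
]

#: convergence tolerance on both the objective and the parameter step
CONVERGENCE_TOL = 1e-8


class AnalysisError(RuntimeError):
    pass


@dataclass(frozen=True)
class TimeSeriesData:
    """Observed (t_i, x_i) pairs of one observable, with optional weights."""

    t: np.ndarray
    x: np.ndarray
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        if t.ndim != 1 or t.shape != x.shape:
            raise ValueError("t and x must be 1-d arrays of equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(x))):
            raise ValueError("observations must be finite")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.shape != t.shape:
                raise ValueError("weights must match the observations")


@dataclass(frozen=True)
class FitResult:
    estimates: ModelParams
    ssr: float
    converged: bool
    n_iter: int
    method: str
    free_params: tuple[str, ...] = field(default=())


def ssr(
    spec: ModelSpec,
    params: ModelParams,
    data: TimeSeriesData,
    observable: str = "C",
    history: Optional[HistorySpec] = None,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> float:
    """Sum of squared residuals of the simulated observable at the data times.

    Integration failures return a large penalty (1e6 x the SSR of the
    flat-zero model) instead of raising, so optimizers stay alive.
    """
    try:
        traj = simulate(
            spec, params, history=history, t_end=float(data.t[-1]) * (1 + 1e-12),
            rel_tol=rel_tol, abs_tol=abs_tol, n_grid=2,
        )
    except (IntegrationError, ValueError) as exc:
        warnings.warn(f"integration failed during SSR evaluation: {exc}", stacklevel=2)
        return 1e6 * float(np.sum(data.x**2))
    sim = traj(data.t)[0 if observable == "C" else 1]
    res = sim - data.x
    if data.weights is not None:
        res = res * np.sqrt(data.weights)
    return float(np.dot(res, res))


def _pack(params: ModelParams, free: Sequence[str]) -> np.ndarray:
    d = params.to_dict()
    return np.array([d[k] for k in free], dtype=float)


def _unpack(params: ModelParams, free: Sequence[str], theta: np.ndarray) -> ModelParams:
    p = params
    for name, value in zip(free, theta):
        p = p.with_value(name, float(value))
    return p


def fit(
    spec: ModelSpec,
    data: TimeSeriesData,
    initial_guess: ModelParams,
    bounds: dict[str, tuple[float, float]],
    free_params: Sequence[str],
    observable: str = "C",
    history: Optional[HistorySpec] = None,
    seed: int = 0,
    max_nm_iter: int = 2000,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> FitResult:
    """Estimate the parameters named in ``free_params`` by least squares.

    ``bounds`` maps each free parameter to its (lower, upper) box; the
    initial guess must lie inside.  Differential evolution (seeded) is
    used as a fallback when Nelder-Mead stalls, followed by a local
    polish.
    """
    free = tuple(free_params)
    for name in free:
        if name not in bounds:
            raise ValueError(f"missing bounds for free parameter {name!r}")
        lo, hi = bounds[name]
        v = initial_guess.to_dict()[name]
        if not (lo <= v <= hi):
            raise ValueError(f"initial {name}={v} outside bounds ({lo}, {hi})")
    box = [tuple(map(float, bounds[k])) for k in free]
    theta0 = _pack(initial_guess, free)

    def objective(theta: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return ssr(spec, _unpack(initial_guess, free, theta), data,
                       observable=observable, history=history,
                       rel_tol=rel_tol, abs_tol=abs_tol)

    nm: OptimizeResult = minimize(
        objective, theta0, method="Nelder-Mead", bounds=box,
        options={"xatol": CONVERGENCE_TOL, "fatol": CONVERGENCE_TOL,
                 "maxiter": max_nm_iter},
    )
    best, method, n_iter = nm, "Nelder-Mead", int(nm.nit)
    if not nm.success:
        de = differential_evolution(
            objective, box, seed=seed, tol=CONVERGENCE_TOL, polish=False,
            init="sobol", maxiter=200,
        )
        polish = minimize(
            objective, de.x, method="Nelder-Mead", bounds=box,
            options={"xatol": CONVERGENCE_TOL, "fatol": CONVERGENCE_TOL,
                     "maxiter": max_nm_iter},
        )
        cand = polish if polish.fun <= de.fun else de
        if cand.fun < best.fun:
            best = cand
            method = "Differential-Evolution+Nelder-Mead"
            n_iter = int(de.nit + getattr(polish, "nit", 0))
    return FitResult(
        estimates=_unpack(initial_guess, free, best.x),
        ssr=float(best.fun),
        converged=bool(best.success if hasattr(best, "success") else True),
        n_iter=n_iter,
        method=method,
        free_params=free,
    )


def first_transient_integral(traj: Trajectory, observable: str = "C") -> float:
    """Integral of the observable from t = 0 to the first minimum after
    the first maximum (trapezoidal rule on the trajectory grid)."""
    x = traj.C if observable == "C" else traj.R
    maxima = argrelextrema(x, np.greater)[0]
    if len(maxima) == 0:
        raise AnalysisError("no local maximum found; simulate longer or check params")
    minima = argrelextrema(x, np.less)[0]
    minima = minima[minima > maxima[0]]
    if len(minima) == 0:
        raise AnalysisError("no local minimum after the first maximum; simulate longer")
    stop = minima[0]
    return float(np.trapezoid(x[: stop + 1], traj.t[: stop + 1]))


def robustness(
    spec: ModelSpec,
    fitted: ModelParams,
    rel_noise: float = 0.10,
    n_draws: int = 100,
    seed: int = 0,
    observable: str = "C",
    t_end: Optional[float] = None,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> float:
    """Relative variation (CV, %) of the first-transient integral under
    independent uniform +/- ``rel_noise`` perturbation of every parameter.

    Raises if more than 10% of the draws fail to simulate or to expose a
    first transient.
    """
    if rel_noise < 0:
        raise ValueError("rel_noise must be >= 0")
    rng = np.random.default_rng(seed)
    if t_end is None:
        t_end = max(10.0 * fitted.tau, 50.0 / fitted.beta)
    d0 = fitted.to_dict()
    names = [k for k, v in d0.items() if v > 0 and k not in ("nu", "kappa")]
    if d0["kappa"] > 0:
        names += ["kappa", "nu"]
    integrals = []
    n_failed = 0
    for _ in range(n_draws):
        p = fitted
        for name in names:
            factor = 1.0 + rel_noise * (2.0 * rng.random() - 1.0)
            value = d0[name] * factor
            if name == "nu":
                value = max(value, 1.0)  # Hill exponent floor of the auto-inhibition
            p = p.with_value(name, value)
        try:
            traj = simulate(spec, p, t_end=t_end, rel_tol=rel_tol, abs_tol=abs_tol)
            integrals.append(first_transient_integral(traj, observable))
        except (IntegrationError, AnalysisError, ValueError):
            n_failed += 1
    if n_failed > 0.1 * n_draws:
        raise AnalysisError(f"{n_failed}/{n_draws} perturbed draws failed")
    arr = np.asarray(integrals)
    if rel_noise == 0:
        return 0.0
    return float(np.std(arr, ddof=1) / np.mean(arr) * 100.0)
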