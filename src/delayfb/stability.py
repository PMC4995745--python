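"""Linear stability of the steady state with respect to the time delay.

Linearizing any of the four designs about its equilibrium yields

    dC/dt = -x C - y R,     dR/dt = C(t - tau) - beta R,

with x > 0 the instantaneous self-damping of C and y >= 0 the gain of
the delayed loop.  The characteristic equation is

    (lambda + x)(lambda + beta) + y exp(-lambda tau) = 0.

Stability criterion:

* x*beta >= y  ->  absolutely stable (stable for every delay tau >= 0);
* x*beta <  y  ->  a Hopf bifurcation occurs at the marginal delay
  tau_m = g / omega, where omega is the critical frequency

      omega^2 = [-(x^2+beta^2) + sqrt((x^2+beta^2)^2 + 4(y^2 - x^2 beta^2))]/2

  and g = arccos((omega^2 - x*beta)/y) on the principal branch.  The
  equilibrium is stable for tau < tau_m and unstable (sustained
  oscillations) for tau >= tau_m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .equilibrium import Equilibrium, EquilibriumError, find_equilibrium
from .models import (
    ModelParams,
    ModelSpec,
    auto_inhibition,
    d_auto_inhibition,
    d_dnf_input_inhibition,
    d_dnf_output_activation,
    dnf_input_inhibition,
    dnf_output_activation,
    validate_pair,
)

__all__ = [
    "LinearizationCoeffs",
    "StabilityResult",
    "linearize",
    "marginal_delay",
    "classify_stability",
    "tau_m_parameter_sweep",
    "bifurcation_vs_input",
]


@dataclass(frozen=True)
class LinearizationCoeffs:
    """Coefficients (x, y, beta) of the linearized delay system."""

    x: float
    y: float
    beta: float

    def __post_init__(self) -> None:
        if self.x <= 0 or self.beta <= 0 or self.y < 0:
            raise ValueError(f"need x, beta > 0 and y >= 0; got {self}")

    @property
    def absolutely_stable(self) -> bool:
        return self.x * self.beta >= self.y


@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the equilibrium -> linearize -> marginal-delay pipeline."""

    classification: str  # "absolutely_stable" | "conditionally_stable"
    coeffs: LinearizationCoeffs
    equilibrium: Equilibrium
    tau_m: Optional[float] = None
    omega: Optional[float] = None


def linearize(spec: ModelSpec, params: ModelParams, eq: Equilibrium) -> LinearizationCoeffs:
    """Evaluate x, y at the equilibrium from the analytic feedback derivatives."""
    validate_pair(spec, params)
    fb = params.feedback
    C_s, R_s = eq.C_s, eq.R_s
    F = auto_inhibition(C_s, fb)
    absFp = abs(d_auto_inhibition(C_s, fb))
    if spec.dnf_mechanism == "input_inhibition":
        S1 = dnf_input_inhibition(R_s, fb)
        absS1p = abs(d_dnf_input_inhibition(R_s, fb))
        if spec.mass_conservation:  # Model 2
            x = params.I * S1 * (F + (1.0 - C_s) * absFp) + params.alpha
            y = params.I * absS1p * (1.0 - C_s) * F
        else:  # Model 1
            x = params.I * S1 * absFp + params.alpha
            y = params.I * absS1p * F
    else:
        S2 = dnf_output_activation(R_s, fb)
        S2p = d_dnf_output_activation(R_s, fb)
        if spec.mass_conservation:  # Model 4
            x = params.I * (F + (1.0 - C_s) * absFp) + params.alpha + params.delta * S2
        else:  # Model 3
            x = params.I * absFp + params.alpha + params.delta * S2
        y = params.delta * C_s * S2p
    return LinearizationCoeffs(x=float(x), y=float(y), beta=params.beta)


def marginal_delay(coeffs: LinearizationCoeffs) -> tuple[float, float]:
    """Marginal delay tau_m and critical frequency omega in the conditional regime.

    Requires x*beta < y; at the returned pair, lambda = i*omega is an
    exact root of the characteristic equation at tau = tau_m.
    """
    x, y, b = coeffs.x, coeffs.y, coeffs.beta
    if x * b >= y:
        raise ValueError(
            f"x*beta={x * b} >= y={y}: absolutely stable, no marginal delay"
        )
    s = x * x + b * b
    root = np.sqrt(s * s + 4.0 * (y * y - x * x * b * b))
    omega2 = 0.5 * (-s + root)
    omega = np.sqrt(omega2)
    arg = (omega2 - x * b) / y
    if abs(arg) > 1.0:
        if abs(arg) > 1.0 + 1e-12:
            raise ArithmeticError(f"arccos argument {arg} outside [-1, 1]")
        arg = float(np.clip(arg, -1.0, 1.0))
    g = np.arccos(arg)
    return float(g / omega), float(omega)


def classify_stability(spec: ModelSpec, params: ModelParams) -> StabilityResult:
    """Full pipeline: steady state, linearization, stability class, tau_m.

    The boundary x*beta = y is classified absolutely stable (criterion
    "x*beta >= y", with exact comparison).
    """
    eq = find_equilibrium(spec, params)
    coeffs = linearize(spec, params, eq)
    if coeffs.absolutely_stable:
        return StabilityResult("absolutely_stable", coeffs, eq)
    tau_m, omega = marginal_delay(coeffs)
    return StabilityResult("conditionally_stable", coeffs, eq, tau_m=tau_m, omega=omega)


def tau_m_parameter_sweep(
    spec: ModelSpec,
    params: ModelParams,
    param_name: str,
    factor_grid: Iterable[float],
) -> pd.DataFrame:
    """tau_m as one parameter is scaled over a grid of multipliers.

    Returns a frame with columns (factor, value, classification, tau_m,
    omega); tau_m is NaN where the scaled set is absolutely stable or the
    equilibrium solve fails, recording where the Hopf point ceases to
    exist.
    """
    rows = []
    base = params.to_dict()[param_name]
    for factor in factor_grid:
        if factor <= 0:
            raise ValueError("factor_grid entries must be > 0")
        p = params.with_value(param_name, base * factor)
        row = {"factor": float(factor), "value": base * factor}
        try:
            res = classify_stability(spec, p)
        except EquilibriumError:
            row.update(classification="failed", tau_m=np.nan, omega=np.nan)
        else:
            row.update(
                classification=res.classification,
                tau_m=res.tau_m if res.tau_m is not None else np.nan,
                omega=res.omega if res.omega is not None else np.nan,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def bifurcation_vs_input(
    spec: ModelSpec, params: ModelParams, I_grid: Iterable[float]
) -> pd.DataFrame:
    """tau_m as a function of the stimulus I (Hopf curve in the (I, tau) plane).

    Variants with auto-inhibition are obtained by passing params whose
    feedback carries the desired (nu, kappa).
    """
    rows = []
    for I in I_grid:
        if I <= 0:
            raise ValueError("I_grid entries must be > 0")
        p = params.with_value("I", float(I))
        try:
            res = classify_stability(spec, p)
        except EquilibriumError:
            rows.append({"I": float(I), "classification": "failed",
                         "tau_m": np.nan, "omega": np.nan})
            continue
        rows.append({
            "I": float(I),
            "classification": res.classification,
            "tau_m": res.tau_m if res.tau_m is not None else np.nan,
            "omega": res.omega if res.omega is not None else np.nan,
        })
    return pd.DataFrame(rows)
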