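"""Steady states of the four DNF designs.

Setting dR/dt = 0 gives R_s = C_s / beta (the delay drops out at steady
state), which reduces the equilibrium condition to a scalar root problem
in C:

    G(C) = production(C, C/beta) - loss(C, C/beta) = 0.

G is strictly decreasing on the admissible interval (production is
non-increasing in C, loss strictly increasing), so the root is unique
and bracketed between C = 0 (where G >= 0) and an upper endpoint where
G < 0: 1 for mass-conservation designs, I/alpha (padded) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .models import ModelParams, ModelSpec, State, rhs, production, loss, validate_pair

__all__ = ["Equilibrium", "find_equilibrium", "EquilibriumError"]


class EquilibriumError(RuntimeError):
    """Steady-state solver could not bracket or refine the root."""


@dataclass(frozen=True)
class Equilibrium:
    """Steady state E = (C_s, R_s) with the residual of both equations."""

    C_s: float
    R_s: float
    residual: float


def _G(C: float, spec: ModelSpec, params: ModelParams) -> float:
    R = C / params.beta
    return production(spec, C, R, params) - loss(spec, C, R, params)


def find_equilibrium(
    spec: ModelSpec, params: ModelParams, tol: float = 1e-12
) -> Equilibrium:
    """Compute the unique non-negative steady state of (spec, params).

    ``tol`` is the absolute residual tolerance on both right-hand sides.
    """
    validate_pair(spec, params)
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if params.I == 0:
        return Equilibrium(0.0, 0.0, 0.0)

    if spec.mass_conservation:
        c_max = 1.0 - 1e-12
    else:
        c_max = params.I / params.alpha * (1.0 + 1e-6)
    g0, g1 = _G(0.0, spec, params), _G(c_max, spec, params)
    if g0 < 0 or g1 > 0:
        raise EquilibriumError(
            f"could not bracket steady state on [0, {c_max}]: G(0)={g0}, G(C_max)={g1}"
        )
    C_s = brentq(_G, 0.0, c_max, args=(spec, params), xtol=1e-15, rtol=8.9e-16)
    R_s = C_s / params.beta
    dC, dR = rhs(spec, State(C_s, R_s), C_s, params)
    residual = max(abs(dC), abs(dR))
    if residual > tol:
        raise EquilibriumError(f"residual {residual} exceeds tol {tol}")
    return Equilibrium(float(C_s), float(R_s), float(residual))


def uniqueness_scan(
    spec: ModelSpec, params: ModelParams, n_grid: int = 1000
) -> int:
    """Count sign changes of G on a grid (diagnostic; 1 expected for I > 0)."""
    c_max = 1.0 if spec.mass_conservation else params.I / params.alpha * (1 + 1e-6)
    grid = np.linspace(0.0, c_max, n_grid)
    vals = np.array([_G(c, spec, params) for c in grid])
    signs = np.sign(vals)
    signs = signs[signs != 0]
    return int(np.sum(signs[1:] != signs[:-1]))
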