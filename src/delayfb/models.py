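"""Two-dimensional delayed negative feedback (DNF) models.

Four generic signal-response networks are covered, all of the form

    dC/dt = production(C, R) - loss(C, R)
    dR/dt = C(t - tau) - beta * R

where a constant stimulus ``I`` drives the component ``C``, which after a
time delay ``tau`` activates the response ``R``; ``R`` closes the delayed
negative feedback either by inhibiting the production of ``C``
(*input-inhibition*, via a reverse Hill function ``S1``) or by enhancing
the degradation of ``C`` (*output-activation*, via a Hill function
``S2``).  Two optional design features modify the loop: *mass
conservation* (C interconverts with an inactive pool of total amount 1,
giving a factor ``(1 - C)`` on production) and an instantaneous
*auto-inhibition* of C via a reverse Hill function ``F(C)``.

Model ids follow the fixed mapping:

    1 = input-inhibition, no mass conservation
    2 = input-inhibition, mass conservation
    3 = output-activation, no mass conservation
    4 = output-activation, mass conservation
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "FeedbackSpec",
    "ModelParams",
    "ModelSpec",
    "State",
    "dnf_input_inhibition",
    "dnf_output_activation",
    "auto_inhibition",
    "d_dnf_input_inhibition",
    "d_dnf_output_activation",
    "d_auto_inhibition",
    "rhs",
    "production",
    "loss",
    "validate_pair",
    "PARAM_NAMES",
]

#: canonical order of the scalar parameter fields (kinetics then feedback)
PARAM_NAMES = ("I", "alpha", "beta", "delta", "tau", "n", "K_m", "nu", "kappa")


class ConfigurationError(ValueError):
    """Model specification and parameters are inconsistent."""


def _check_nonneg(name: str, value: float) -> None:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class FeedbackSpec:
    """Shape parameters of the feedback nonlinearities.

    Parameters
    ----------
    n : Hill coefficient of the DNF (abruptness).  Values below 1 are
        accepted with a warning: the Monte-Carlo weak-feedback protocol
        deliberately samples ``n`` down to 0.1x its base value.
    K_m : half-saturation constant of the DNF (activation threshold), > 0.
    nu : Hill coefficient of the auto-inhibition, >= 1.
    kappa : auto-inhibition scale, >= 0.  ``kappa = 0`` disables the
        auto-inhibition entirely (``F(C) = 1``).
    """

    n: float = 1.0
    K_m: float = 1.0
    nu: float = 1.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.K_m) or self.K_m <= 0:
            raise ValueError(f"K_m must be > 0, got {self.K_m!r}")
        if not np.isfinite(self.n) or self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n!r}")
        if self.n < 1:
            warnings.warn(
                f"Hill coefficient n={self.n} < 1: outside the nominal n >= 1 "
                "regime (allowed for weak-feedback sampling)",
                stacklevel=3,
            )
        if not np.isfinite(self.nu) or self.nu < 1:
            raise ValueError(f"nu must be >= 1, got {self.nu!r}")
        _check_nonneg("kappa", self.kappa)


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of a DNF model.

    ``I`` is the constant input stimulus, ``alpha`` the basal
    degradation/back-conversion rate of C, ``beta`` the degradation rate
    of R, ``delta`` the feedback-mediated degradation rate of C (only
    meaningful for output-activation; must be 0 for Models 1-2), ``tau``
    the time delay.  All rates are in 1/time in arbitrary units.
    """

    I: float
    alpha: float
    beta: float
    delta: float = 0.0
    tau: float = 0.0
    feedback: FeedbackSpec = field(default_factory=FeedbackSpec)

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha!r}")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta!r}")
        _check_nonneg("delta", self.delta)
        _check_nonneg("I", self.I)
        _check_nonneg("tau", self.tau)

    def to_dict(self) -> dict[str, float]:
        fb = self.feedback
        return {
            "I": self.I, "alpha": self.alpha, "beta": self.beta,
            "delta": self.delta, "tau": self.tau,
            "n": fb.n, "K_m": fb.K_m, "nu": fb.nu, "kappa": fb.kappa,
        }

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParams":
        fb = FeedbackSpec(
            n=float(d.get("n", 1.0)), K_m=float(d.get("K_m", 1.0)),
            nu=float(d.get("nu", 1.0)), kappa=float(d.get("kappa", 0.0)),
        )
        return cls(
            I=float(d["I"]), alpha=float(d["alpha"]), beta=float(d["beta"]),
            delta=float(d.get("delta", 0.0)), tau=float(d.get("tau", 0.0)),
            feedback=fb,
        )

    def with_value(self, name: str, value: float) -> "ModelParams":
        """Return a copy with one named scalar parameter replaced."""
        if name in ("n", "K_m", "nu", "kappa"):
            return replace(self, feedback=replace(self.feedback, **{name: value}))
        if name in ("I", "alpha", "beta", "delta", "tau"):
            return replace(self, **{name: value})
        raise KeyError(f"unknown parameter {name!r}")


Mechanism = Literal["input_inhibition", "output_activation"]

_MODEL_TABLE: dict[int, tuple[Mechanism, bool]] = {
    1: ("input_inhibition", False),
    2: ("input_inhibition", True),
    3: ("output_activation", False),
    4: ("output_activation", True),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the four network designs, identified by ``model_id`` 1-4."""

    model_id: int

    def __post_init__(self) -> None:
        if self.model_id not in _MODEL_TABLE:
            raise ValueError(f"model_id must be in {{1,2,3,4}}, got {self.model_id!r}")

    @property
    def dnf_mechanism(self) -> Mechanism:
        return _MODEL_TABLE[self.model_id][0]

    @property
    def mass_conservation(self) -> bool:
        return _MODEL_TABLE[self.model_id][1]

    @classmethod
    def from_flags(cls, mechanism: Mechanism, mass_conservation: bool) -> "ModelSpec":
        for mid, flags in _MODEL_TABLE.items():
            if flags == (mechanism, mass_conservation):
                return cls(mid)
        raise ValueError(f"no model with {mechanism=}, {mass_conservation=}")


@dataclass(frozen=True)
class State:
    """Instantaneous state (C, R) of a model."""

    C: float
    R: float

    def validate(self, spec: ModelSpec) -> None:
        _check_nonneg("C", self.C)
        _check_nonneg("R", self.R)
        if spec.mass_conservation and self.C > 1:
            raise ValueError(
                f"C={self.C} exceeds the conserved total of 1 for model {spec.model_id}"
            )


def validate_pair(spec: ModelSpec, params: ModelParams) -> None:
    """Raise ConfigurationError if params are inconsistent with the design."""
    if spec.dnf_mechanism == "input_inhibition" and params.delta != 0:
        raise ConfigurationError(
            f"delta={params.delta} must be 0 for input-inhibition models "
            f"(model {spec.model_id})"
        )


def _pow(base, exponent):
    # real power of non-negative base; 0**e defined as 0 for e > 0
    return np.power(base, exponent)


def dnf_input_inhibition(R, fb: FeedbackSpec):
    """Reverse Hill function S1(R) = K_m^n / (K_m^n + R^n), in (0, 1].

    Monotonically decreasing: the response R inhibits the production of C.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be >= 0")
    # divide by K_m^n for overflow safety with large n
    ratio = _pow(R / fb.K_m, fb.n)
    out = 1.0 / (1.0 + ratio)
    return out if out.ndim else float(out)


def dnf_output_activation(R, fb: FeedbackSpec):
    """Hill function S2(R) = R^n / (K_m^n + R^n), in [0, 1).

    Monotonically increasing; with shared (n, K_m), S2 = 1 - S1.
    """
    R = np.asarray(R, dtype=float)
    if np.any(R < 0):
        raise ValueError("R must be >= 0")
    ratio = _pow(R / fb.K_m, fb.n)
    out = ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def auto_inhibition(C, fb: FeedbackSpec):
    """Auto-inhibitory reverse Hill function F(C) = 1 / (1 + (kappa*C)^nu)."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be >= 0")
    out = 1.0 / (1.0 + _pow(fb.kappa * C, fb.nu))
    return out if out.ndim else float(out)


def d_dnf_input_inhibition(R: float, fb: FeedbackSpec) -> float:
    """Analytic derivative S1'(R) = -n K_m^n R^(n-1) / (K_m^n + R^n)^2 (<= 0)."""
    if R < 0:
        raise ValueError("R must be >= 0")
    if R == 0:
        # limit: 0 for n > 1, -n/K_m for n = 1, divergent for n < 1
        if fb.n > 1:
            return 0.0
        if fb.n == 1:
            return -1.0 / fb.K_m
        return -np.inf
    s1 = dnf_input_inhibition(R, fb)
    s2 = 1.0 - s1
    return -fb.n / R * s1 * s2


def d_dnf_output_activation(R: float, fb: FeedbackSpec) -> float:
    """Analytic derivative S2'(R) = -S1'(R) (>= 0)."""
    return -d_dnf_input_inhibition(R, fb)


def d_auto_inhibition(C: float, fb: FeedbackSpec) -> float:
    """Analytic derivative F'(C) = -nu*kappa*(kappa C)^(nu-1) * F(C)^2 (<= 0)."""
    if C < 0:
        raise ValueError("C must be >= 0")
    if fb.kappa == 0:
        return 0.0
    f = auto_inhibition(C, fb)
    return -fb.nu * fb.kappa * _pow(fb.kappa * C, fb.nu - 1.0) * f * f


def production(spec: ModelSpec, C: float, R: float, params: ModelParams) -> float:
    """Production term of dC/dt (everything except the loss terms)."""
    fb = params.feedback
    F = auto_inhibition(C, fb)
    if spec.dnf_mechanism == "input_inhibition":
        prod = params.I * dnf_input_inhibition(R, fb) * F
    else:
        prod = params.I * F
    if spec.mass_conservation:
        prod *= 1.0 - C
    return prod


def loss(spec: ModelSpec, C: float, R: float, params: ModelParams) -> float:
    """Loss term of dC/dt: alpha*C plus, for output-activation, delta*C*S2(R)."""
    out = params.alpha * C
    if spec.dnf_mechanism == "output_activation":
        out += params.delta * C * dnf_output_activation(R, params.feedback)
    return out


def rhs(
    spec: ModelSpec,
    state: State,
    delayed_C: float,
    params: ModelParams,
) -> tuple[float, float]:
    """Evaluate (dC/dt, dR/dt) for the chosen design.

    ``delayed_C`` is the value C(t - tau) entering the activation of R;
    dR/dt = C(t - tau) - beta*R identically across all four models.
    """
    validate_pair(spec, params)
    state.validate(spec)
    if delayed_C < 0:
        raise ValueError("delayed_C must be >= 0")
    dC = production(spec, state.C, state.R, params) - loss(spec, state.C, state.R, params)
    dR = delayed_C - params.beta * state.R
    return float(dC), float(dR)
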