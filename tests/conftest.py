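import numpy as np
import pytest

from delayfb.models import ModelSpec
from delayfb.presets import ALTERNATIVE_SET, PRIMARY_SET, params_for_model


@pytest.fixture(scope="session")
def primary():
    return PRIMARY_SET


@pytest.fixture(scope="session")
def alternative():
    return ALTERNATIVE_SET


@pytest.fixture(params=[1, 2, 3, 4], ids=lambda m: f"model{m}")
def any_model(request):
    return ModelSpec(request.param)


def fixture_params(model_id: int, base, **overrides):
    """Base parameter vector adapted to a model, with optional overrides."""
    spec = ModelSpec(model_id)
    p = params_for_model(spec, base)
    for k, v in overrides.items():
        p = p.with_value(k, v)
    return spec, p


def char_residual(x: float, y: float, beta: float, omega: float, tau: float) -> float:
    """|(i*omega + x)(i*omega + beta) + y*exp(-i*omega*tau)|: zero at a Hopf root."""
    lam = 1j * omega
    return abs((lam + x) * (lam + beta) + y * np.exp(-lam * tau))


def dominant_root(x: float, y: float, beta: float, tau: float, omega0: float) -> complex:
    """Newton refinement of the characteristic root near i*omega0 at delay tau.

    Independent of the closed-form marginal-delay expressions; used to
    predict envelope growth/decay rates for simulation cross-checks.
    """
    lam = 0.0 + 1j * omega0
    for _ in range(100):
        f = (lam + x) * (lam + beta) + y * np.exp(-lam * tau)
        df = 2 * lam + x + beta - tau * y * np.exp(-lam * tau)
        step = f / df
        lam -= step
        if abs(step) < 1e-13:
            break
    return lam
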