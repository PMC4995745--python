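"""Linearization, stability classification and marginal delay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import char_residual, fixture_params
from delayfb.equilibrium import find_equilibrium
from delayfb.models import (
    ConfigurationError,
    FeedbackSpec,
    ModelParams,
    ModelSpec,
    State,
    rhs,
)
from delayfb.presets import ALTERNATIVE_SET, PRIMARY_SET
from delayfb.stability import (
    LinearizationCoeffs,
    bifurcation_vs_input,
    classify_stability,
    linearize,
    marginal_delay,
    tau_m_parameter_sweep,
)


class TestLinearize:
    def test_no_feedback_at_all(self):
        # Model 3, delta=0, kappa=0: open loop, x = alpha, y = 0
        p = ModelParams(I=0.87, alpha=0.11, beta=0.17, delta=0.0)
        spec = ModelSpec(3)
        c = linearize(spec, p, find_equilibrium(spec, p))
        assert c.x == pytest.approx(p.alpha)
        assert c.y == 0.0
        assert c.absolutely_stable

    def test_model1_without_auto_inhibition(self):
        from delayfb.models import d_dnf_input_inhibition

        spec, p = fixture_params(1, PRIMARY_SET)
        eq = find_equilibrium(spec, p)
        c = linearize(spec, p, eq)
        assert c.x == pytest.approx(p.alpha)  # F' == 0 when kappa = 0
        assert c.y == pytest.approx(p.I * abs(d_dnf_input_inhibition(eq.R_s, p.feedback)))

    def test_spec_params_mismatch_raises(self):
        p = ModelParams(I=1.0, alpha=1.0, beta=1.0, delta=3.0)
        eq = find_equilibrium(ModelSpec(3), p)
        with pytest.raises(ConfigurationError):
            linearize(ModelSpec(1), p, eq)

    @pytest.mark.parametrize("model_id", [1, 2, 3, 4])
    @pytest.mark.parametrize("kappa", [0.0, 1.73])
    def test_matches_finite_difference_jacobian(self, model_id, kappa):
        """x = -d(dC/dt)/dC and y = -d(dC/dt)/dR at the equilibrium."""
        base = PRIMARY_SET.with_value("kappa", kappa).with_value("nu", 3.0)
        spec, p = fixture_params(model_id, base)
        eq = find_equilibrium(spec, p)
        c = linearize(spec, p, eq)
        h = 1e-6

        def dC(C, R):
            return rhs(spec, State(C, R), eq.C_s, p)[0]

        x_fd = -(dC(eq.C_s + h, eq.R_s) - dC(eq.C_s - h, eq.R_s)) / (2 * h)
        y_fd = -(dC(eq.C_s, eq.R_s + h) - dC(eq.C_s, eq.R_s - h)) / (2 * h)
        assert c.x == pytest.approx(x_fd, rel=1e-6, abs=1e-8)
        assert c.y == pytest.approx(y_fd, rel=1e-6, abs=1e-8)


class TestMarginalDelay:
    def test_symmetric_closed_form(self):
        tau_m, omega = marginal_delay(LinearizationCoeffs(x=1.0, y=2.0, beta=1.0))
        assert omega == pytest.approx(1.0)
        assert tau_m == pytest.approx(np.pi / 2)

    def test_characteristic_equation_root(self):
        c = LinearizationCoeffs(x=0.5, y=0.3, beta=0.2)
        tau_m, omega = marginal_delay(c)
        assert char_residual(c.x, c.y, c.beta, omega, tau_m) < 1e-10

    def test_absolutely_stable_regime_rejected(self):
        with pytest.raises(ValueError, match="absolutely stable"):
            marginal_delay(LinearizationCoeffs(x=1.0, y=0.5, beta=1.0))

    @given(
        x=st.floats(0.02, 10.0),
        beta=st.floats(0.02, 10.0),
        excess=st.floats(1.001, 50.0),
    )
    @settings(derandomize=True, max_examples=80)
    def test_purely_imaginary_root_property(self, x, beta, excess):
        c = LinearizationCoeffs(x=x, y=excess * x * beta, beta=beta)
        tau_m, omega = marginal_delay(c)
        assert tau_m > 0 and omega > 0
        assert char_residual(c.x, c.y, c.beta, omega, tau_m) < 1e-9

    def test_monotone_in_x_and_y(self):
        """tau_m increases with the self-damping x, decreases with the loop gain y."""
        rng = np.random.default_rng(42)
        h = 1e-4
        for _ in range(20):
            x = rng.uniform(0.05, 5.0)
            beta = rng.uniform(0.05, 5.0)
            y = x * beta * rng.uniform(1.05, 20.0)
            t0, _ = marginal_delay(LinearizationCoeffs(x, y, beta))
            t_x, _ = marginal_delay(LinearizationCoeffs(x + h, y, beta))
            t_y, _ = marginal_delay(LinearizationCoeffs(x, y + h, beta))
            assert t_x > t0
            assert t_y < t0

    def test_diverges_at_absolute_stability_boundary(self):
        x = beta = 1.0
        t_near, _ = marginal_delay(LinearizationCoeffs(x, x * beta * (1 + 1e-6), beta))
        t_far, _ = marginal_delay(LinearizationCoeffs(x, 2 * x * beta, beta))
        assert t_near > 100 * t_far


class TestClassification:
    def test_boundary_is_absolutely_stable(self):
        assert LinearizationCoeffs(x=1.0, y=1.0, beta=1.0).absolutely_stable
        assert LinearizationCoeffs(x=1.0, y=0.5, beta=1.0).absolutely_stable
        assert not LinearizationCoeffs(x=1.0, y=1.0 + 1e-15, beta=1.0).absolutely_stable

    def test_model4_alternative_set(self):
        spec, p = fixture_params(4, ALTERNATIVE_SET)
        res = classify_stability(spec, p)
        assert res.classification == "conditionally_stable"
        # printed value 0.52 (our exact value for the printed inputs: 0.5083)
        assert res.tau_m == pytest.approx(0.52, abs=0.02)
        assert char_residual(res.coeffs.x, res.coeffs.y, p.beta, res.omega, res.tau_m) < 1e-10


class TestSweeps:
    def test_degenerate_grid_reproduces_classification(self):
        spec, p = fixture_params(1, PRIMARY_SET)
        res = classify_stability(spec, p)
        df = tau_m_parameter_sweep(spec, p, "K_m", [1.0])
        assert df.loc[0, "tau_m"] == pytest.approx(res.tau_m)
        df_i = bifurcation_vs_input(spec, p, [p.I])
        assert df_i.loc[0, "tau_m"] == pytest.approx(res.tau_m)

    def test_raising_activation_threshold_stabilizes(self):
        """tau_m grows with K_m and the Hopf point eventually disappears."""
        spec, p = fixture_params(1, PRIMARY_SET)
        df = tau_m_parameter_sweep(spec, p, "K_m", [1, 10, 100, 1000, 10000])
        finite = df["tau_m"].dropna()
        assert np.all(np.diff(finite.values) > 0)
        assert df["classification"].iloc[-1] == "absolutely_stable"

    def test_auto_inhibition_raises_marginal_delay(self):
        """Steepening F at the equilibrium widens the stable delay range."""
        spec, p = fixture_params(3, ALTERNATIVE_SET)
        p_ai = p.with_value("nu", 3.0).with_value("kappa", 1.73)
        t0 = classify_stability(spec, p).tau_m
        t1 = classify_stability(spec, p_ai).tau_m
        assert t1 > t0
        df = tau_m_parameter_sweep(spec, p_ai, "kappa", [0.1, 0.5, 1.0, 2.0])
        assert np.all(np.diff(df["tau_m"].values) > 0)

    def test_bifurcation_curve_decreases_with_input(self):
        # stronger stimulus destabilizes: tau_m falls as I rises toward the
        # base value (the curve levels off well above it)
        spec, p = fixture_params(3, ALTERNATIVE_SET)
        df = bifurcation_vs_input(spec, p, [0.2, 0.35, 0.5, 0.75, 1.0])
        assert np.all(np.diff(df["tau_m"].values) < 0)
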