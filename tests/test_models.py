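"""Feedback nonlinearities and model right-hand sides."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delayfb.models import (
    ConfigurationError,
    FeedbackSpec,
    ModelParams,
    ModelSpec,
    State,
    auto_inhibition,
    d_auto_inhibition,
    d_dnf_input_inhibition,
    dnf_input_inhibition,
    dnf_output_activation,
    rhs,
)
from delayfb.presets import PRIMARY_SET

FB = FeedbackSpec(n=12.77, K_m=0.23)


class TestFeedbackFunctions:
    def test_input_inhibition_anchors(self):
        assert dnf_input_inhibition(0.0, FB) == 1.0
        assert dnf_input_inhibition(FB.K_m, FB) == pytest.approx(0.5)

    def test_output_activation_anchors(self):
        assert dnf_output_activation(0.0, FB) == 0.0
        assert dnf_output_activation(FB.K_m, FB) == pytest.approx(0.5)

    def test_input_inhibition_arithmetic_value(self):
        # independent arithmetic evaluation at R=0.46, n=12.77, K_m=0.23
        import math

        expected = math.pow(0.23, 12.77) / (math.pow(0.23, 12.77) + math.pow(0.46, 12.77))
        assert dnf_input_inhibition(0.46, FB) == pytest.approx(expected, rel=1e-14)
        # symmetry identity cross-check
        assert dnf_input_inhibition(0.46, FB) == pytest.approx(
            1.0 - dnf_output_activation(0.46, FB), rel=1e-12
        )

    @given(R=st.floats(0.0, 50.0), n=st.floats(0.5, 20.0), K_m=st.floats(0.01, 10.0))
    @settings(derandomize=True, max_examples=60)
    def test_s1_s2_partition_of_unity(self, R, n, K_m):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fb = FeedbackSpec(n=n, K_m=K_m)
        assert dnf_input_inhibition(R, fb) + dnf_output_activation(R, fb) == pytest.approx(1.0)

    def test_monotonicity_on_grid(self):
        fb = FeedbackSpec(n=2.0, K_m=0.5)
        grid = np.linspace(0.0, 5.0, 400)
        s1 = dnf_input_inhibition(grid, fb)
        s2 = dnf_output_activation(grid, fb)
        assert np.all(np.diff(s1) < 0)
        assert np.all(np.diff(s2) > 0)
        assert np.all((s1 > 0) & (s1 <= 1))
        # steep fixture set: non-increasing even where powers underflow
        s1_steep = dnf_input_inhibition(grid, FB)
        assert np.all(np.diff(s1_steep) <= 0)

    def test_auto_inhibition_disabled_and_halfpoint(self):
        fb0 = FeedbackSpec(kappa=0.0, nu=3.0)
        assert auto_inhibition(123.4, fb0) == 1.0
        fb = FeedbackSpec(kappa=1.73, nu=3.0)
        assert auto_inhibition(1.0 / 1.73, fb) == pytest.approx(0.5)
        grid = np.linspace(0.0, 10.0, 200)
        F = auto_inhibition(grid, fb)
        assert np.all((F > 0) & (F <= 1))
        assert np.all(np.diff(F) <= 0)

    def test_auto_inhibition_derivative_vs_finite_difference(self):
        fb = FeedbackSpec(kappa=1.73, nu=3.0)
        C, h = 0.5, 1e-6
        fd = (auto_inhibition(C + h, fb) - auto_inhibition(C - h, fb)) / (2 * h)
        assert d_auto_inhibition(C, fb) == pytest.approx(fd, rel=1e-8)
        # analytic form nu*kappa*(kappa C)^(nu-1)*F^2
        F = auto_inhibition(C, fb)
        assert abs(d_auto_inhibition(C, fb)) == pytest.approx(
            fb.nu * fb.kappa * (fb.kappa * C) ** (fb.nu - 1) * F**2
        )

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            dnf_input_inhibition(-0.1, FB)
        with pytest.raises(ValueError):
            dnf_output_activation(-0.1, FB)
        with pytest.raises(ValueError):
            auto_inhibition(-0.1, FB)
        with pytest.raises(ValueError):
            d_dnf_input_inhibition(-0.1, FB)

    def test_hill_coefficient_below_one_warns(self):
        with pytest.warns(UserWarning, match="n=0.5"):
            FeedbackSpec(n=0.5, K_m=1.0)


class TestRhs:
    def test_model1_from_rest(self):
        p = ModelParams(I=0.87, alpha=0.11, beta=0.17, feedback=FB)
        dC, dR = rhs(ModelSpec(1), State(0.0, 0.0), 0.0, p)
        assert (dC, dR) == (pytest.approx(0.87), 0.0)

    @pytest.mark.parametrize("R", [0.0, 0.3, 2.0])
    def test_mass_conservation_kills_production_at_full_pool(self, R):
        p = ModelParams(I=0.87, alpha=0.11, beta=0.17, feedback=FB)
        dC, _ = rhs(ModelSpec(2), State(1.0, R), 0.5, p)
        assert dC == pytest.approx(-p.alpha)

    def test_equilibrium_is_a_fixed_point(self):
        from delayfb.equilibrium import find_equilibrium

        spec = ModelSpec(3)
        eq = find_equilibrium(spec, PRIMARY_SET)
        dC, dR = rhs(spec, State(eq.C_s, eq.R_s), eq.C_s, PRIMARY_SET)
        assert abs(dC) < 1e-12 and abs(dR) < 1e-12

    def test_delta_forbidden_for_input_inhibition(self):
        p = ModelParams(I=1.0, alpha=1.0, beta=1.0, delta=2.0)
        with pytest.raises(ConfigurationError):
            rhs(ModelSpec(1), State(0.1, 0.1), 0.1, p)

    @given(
        model_id=st.sampled_from([2, 4]),
        I=st.floats(0.01, 5.0),
        alpha=st.floats(0.01, 5.0),
        beta=st.floats(0.01, 5.0),
        delta=st.floats(0.0, 100.0),
        R=st.floats(0.0, 10.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_unit_interval_forward_invariance(self, model_id, I, alpha, beta, delta, R):
        """dC/dt points inward at both ends of [0, 1] under mass conservation."""
        spec = ModelSpec(model_id)
        p = ModelParams(
            I=I, alpha=alpha, beta=beta,
            delta=delta if spec.dnf_mechanism == "output_activation" else 0.0,
            feedback=FB,
        )
        dC_low, _ = rhs(spec, State(0.0, R), 0.0, p)
        dC_high, _ = rhs(spec, State(1.0, R), 0.0, p)
        assert dC_low >= 0.0
        assert dC_high <= 0.0
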