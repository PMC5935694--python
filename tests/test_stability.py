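import math

import numpy as np
import pytest

from lvimm import (
    Classification,
    LVParameters,
    ModelSpec,
    State,
    beta_criterion,
    classify,
    equilibrium_closed_form,
    equilibrium_numeric,
    gamma_closed_form,
    jacobian_analytic,
    model_for_case,
    rhs_xy,
)
from lvimm.equilibria import Equilibrium

from conftest import random_type1_params


def finite_difference_jacobian(model, x, y, eps=1e-7):
    J = np.empty((2, 2))
    for j, (dx, dy) in enumerate(((eps, 0.0), (0.0, eps))):
        fp = rhs_xy(x + dx, y + dy, model)
        fm = rhs_xy(x - dx, y - dy, model)
        J[0, j] = (fp[0] - fm[0]) / (2 * eps)
        J[1, j] = (fp[1] - fm[1]) / (2 * eps)
    return J


class TestJacobian:
    def test_classical_center_form(self, fig1_params):
        p = fig1_params
        model = ModelSpec(params=p)
        J = jacobian_analytic(model, State(p.m / p.b, p.r / p.a))
        expected = np.array([[0.0, -p.a * p.m / p.b], [p.b * p.r / p.a, 0.0]])
        np.testing.assert_allclose(J, expected, atol=1e-14)

    def test_case_a1_j11(self, fig1_params):
        # J11 = r - a*y* = -b*c/m at the shifted equilibrium
        model = model_for_case(fig1_params, "A1", 0.01)
        eq = equilibrium_closed_form(fig1_params, "A1", 0.01)
        J = jacobian_analytic(model, State(eq.x_star, eq.y_star))
        assert J[0, 0] == pytest.approx(-0.015, rel=1e-12)

    def test_case_c1_j11(self, fig1_params):
        # J11 = (r - a*y*) - c/x*^2 = -2*b^2*c/m^2
        model = model_for_case(fig1_params, "C1", 0.01)
        eq = equilibrium_closed_form(fig1_params, "C1", 0.01)
        J = jacobian_analytic(model, State(eq.x_star, eq.y_star))
        assert J[0, 0] == pytest.approx(-0.045, rel=1e-12)

    @pytest.mark.parametrize("case", ["classical", "A1", "B1", "C1", "D1"])
    def test_matches_finite_differences_type1(self, rng, case):
        for _ in range(10):
            params = random_type1_params(rng)
            mag = 0.0 if case == "classical" else rng.uniform(0.001, 0.05)
            model = model_for_case(params, case, mag)
            x, y = rng.uniform(0.5, 5.0, size=2)
            J = jacobian_analytic(model, State(x, y))
            J_fd = finite_difference_jacobian(model, x, y)
            np.testing.assert_allclose(J, J_fd, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_matches_finite_differences_saturating(self, rng, alpha):
        for _ in range(10):
            r, a, b, m = rng.uniform(0.05, 1.0, size=4)
            params = LVParameters(r=r, a=a, b=b, m=m, h=rng.uniform(0.01, 0.5),
                                  alpha=alpha)
            model = ModelSpec(params=params)
            x, y = rng.uniform(0.5, 5.0, size=2)
            J = jacobian_analytic(model, State(x, y))
            J_fd = finite_difference_jacobian(model, x, y)
            np.testing.assert_allclose(J, J_fd, rtol=1e-6, atol=1e-9)

    def test_random_pulse_unsupported(self, random_pulse_model):
        with pytest.raises(ValueError):
            jacobian_analytic(random_pulse_model, State(1.0, 1.0))

    def test_nonpositive_point_rejected(self, fig1_params):
        with pytest.raises(ValueError):
            jacobian_analytic(ModelSpec(params=fig1_params), State(0.0, 1.0))


class TestGammaClosedForm:
    @pytest.mark.parametrize(
        "case,expected",
        [("A1", 0.0075), ("B1", 0.005), ("C1", 0.0225), ("D1", 0.01)],
    )
    def test_values(self, fig1_params, case, expected):
        assert gamma_closed_form(fig1_params, 0.01, case) == pytest.approx(expected, rel=1e-12)

    def test_zero_magnitude(self, fig1_params):
        for case in ("A1", "B1", "C1", "D1"):
            assert gamma_closed_form(fig1_params, 0.0, case) == 0.0

    def test_unknown_case(self, fig1_params):
        with pytest.raises(ValueError):
            gamma_closed_form(fig1_params, 0.01, "classical")

    @pytest.mark.parametrize("case", ["A1", "B1", "C1", "D1"])
    def test_strictly_increasing_in_magnitude(self, fig1_params, case):
        vals = [gamma_closed_form(fig1_params, mag, case)
                for mag in (0.001, 0.01, 0.1)]
        assert vals[0] < vals[1] < vals[2]


class TestBetaCriterion:
    def test_fig4_value(self, type3_params):
        assert beta_criterion(type3_params) == pytest.approx(0.028, rel=1e-12)

    def test_boundary(self):
        p = LVParameters(r=0.1, a=0.1, b=0.3, m=0.2, h=1.5)  # h = b/m
        assert beta_criterion(p) == pytest.approx(0.0, abs=1e-15)

    def test_type1_limit_positive(self, fig1_params):
        assert beta_criterion(fig1_params) == pytest.approx(
            fig1_params.r * fig1_params.b)


class TestClassify:
    def test_classical_neutral_center(self, fig1_params):
        model = ModelSpec(params=fig1_params)
        eq = equilibrium_closed_form(fig1_params, "classical")
        rep = classify(model, eq)
        assert rep.classification is Classification.NEUTRAL_CENTER
        assert abs(rep.eigenvalues.real).max() <= 1e-12
        freq = math.sqrt(fig1_params.r * fig1_params.m)
        np.testing.assert_allclose(np.sort(rep.eigenvalues.imag),
                                   [-freq, freq], rtol=1e-8)

    def test_type2_unstable(self, type2_params):
        model = ModelSpec(params=type2_params)
        rep = classify(model, equilibrium_numeric(model))
        assert rep.classification is Classification.UNSTABLE
        assert rep.trace == pytest.approx(0.006667, abs=1e-6)

    def test_type3_stable_with_positive_beta(self, type3_params):
        model = ModelSpec(params=type3_params)
        rep = classify(model, equilibrium_numeric(model))
        assert rep.classification is Classification.ASYMPTOTICALLY_STABLE
        assert rep.trace == pytest.approx(-0.0867, abs=1e-4)
        assert rep.determinant > 0
        assert beta_criterion(type3_params) > 0

    def test_migration_case_a2_not_stable(self, fig1_params):
        model = model_for_case(fig1_params, "A2", 0.01)
        eq = equilibrium_numeric(model)
        rep = classify(model, eq)
        assert rep.classification is not Classification.ASYMPTOTICALLY_STABLE

    def test_infeasible_short_circuits(self, fig1_params):
        model = model_for_case(fig1_params, "B1", 0.25)
        eq = equilibrium_closed_form(fig1_params, "B1", 0.25)
        rep = classify(model, eq)
        assert rep.classification is Classification.INFEASIBLE

    def test_trace_det_eigenvalue_consistency(self, rng):
        for _ in range(20):
            params = random_type1_params(rng)
            model = model_for_case(params, "A1", 0.01)
            eq = equilibrium_closed_form(params, "A1", 0.01)
            rep = classify(model, eq)
            assert rep.trace == pytest.approx(rep.eigenvalues.sum().real, rel=1e-10, abs=1e-14)
            assert rep.determinant == pytest.approx(np.prod(rep.eigenvalues).real, rel=1e-10, abs=1e-14)


class TestGammaEigenvalueIdentity:
    @pytest.mark.parametrize("case", ["A1", "B1", "C1", "D1"])
    def test_identity_random_grid(self, rng, case):
        checked = 0
        while checked < 20:
            params = random_type1_params(rng)
            mag = rng.uniform(0.001, 0.1) * min(params.r, params.m)
            eq = equilibrium_closed_form(params, case, mag)
            if not eq.feasible:
                continue
            model = model_for_case(params, case, mag)
            rep = classify(model, eq)
            gamma = gamma_closed_form(params, mag, case)
            if rep.eigenvalues.imag.max() <= 0:
                continue  # overdamped draw: identity holds for the focus regime
            assert rep.gamma_numeric == pytest.approx(gamma, rel=1e-8)
            checked += 1

    @pytest.mark.parametrize("case", ["A1", "B1", "C1", "D1"])
    def test_sign_flip_destabilizes(self, rng, case):
        flipped = {"A1": "A2", "B1": "B2", "C1": "C2", "D1": "D2"}[case]
        for _ in range(10):
            params = random_type1_params(rng)
            mag = 0.01 * min(params.r, params.m)
            eq_in = equilibrium_closed_form(params, case, mag)
            if not eq_in.feasible:
                continue
            rep_in = classify(model_for_case(params, case, mag), eq_in)
            assert rep_in.classification is Classification.ASYMPTOTICALLY_STABLE
            model_out = model_for_case(params, flipped, mag)
            eq_out = equilibrium_numeric(model_out)
            rep_out = classify(model_out, eq_out)
            assert rep_out.classification is not Classification.ASYMPTOTICALLY_STABLE
            if rep_out.classification is not Classification.INFEASIBLE:
                # constant/density outflow perturbs the trace the opposite way
                assert rep_out.trace > 0
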