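"""Coexistence equilibria: closed forms for the linear-response cases, numeric
root-finding for the saturating responses.

Closed-form case labels (linear response only):

==========  ==========================  =====================================
label       immigration                 equilibrium (x*, y*)
==========  ==========================  =====================================
classical   none                        (m/b, r/a)
A1          prey constant c             (m/b, (m r + b c)/(a m))
B1          predator constant d         ((m r - a d)/(b r), r/a),  m r > a d
C1          prey density-dep. c/x       (m/b, (m^2 r + b^2 c)/(a m^2))
D1          predator density-dep. d/y   ((m r^2 - a^2 d)/(b r^2), r/a),
                                        m r^2 > a^2 d
==========  ==========================  =====================================
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from .model import (
    ImmigrationSpec,
    LVParameters,
    ModelSpec,
    rhs_xy,
    unguarded_field,
)

__all__ = [
    "Equilibrium",
    "UnsupportedCaseError",
    "NoConvergenceError",
    "CLOSED_FORM_CASES",
    "model_for_case",
    "equilibrium_closed_form",
    "equilibrium_numeric",
]

RESIDUAL_TOL = 1e-10

CLOSED_FORM_CASES = ("classical", "A1", "B1", "C1", "D1")

# Case -> (side, mode, sign): how the single immigration term enters.
_CASE_TERMS = {
    "classical": None,
    "A1": ("prey", "constant", +1),
    "B1": ("pred", "constant", +1),
    "C1": ("prey", "density_dependent", +1),
    "D1": ("pred", "density_dependent", +1),
    "A2": ("prey", "constant", -1),
    "B2": ("pred", "constant", -1),
    "C2": ("prey", "density_dependent", -1),
    "D2": ("pred", "density_dependent", -1),
}


class UnsupportedCaseError(ValueError):
    """Closed forms exist only for the linear response cases."""


class NoConvergenceError(RuntimeError):
    """The numeric root search exhausted its retry ladder."""


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point with provenance and feasibility."""

    x_star: float
    y_star: float
    case_label: str
    feasible: bool
    residual: float


def model_for_case(
    params: LVParameters, case_label: str, magnitude: float = 0.0
) -> ModelSpec:
    """Assemble the ModelSpec whose single immigration term matches a case label.

    Accepts the migration labels A2-D2 as the sign-flipped counterparts.
    """
    if case_label not in _CASE_TERMS:
        raise ValueError(f"unknown case label {case_label!r}")
    term = _CASE_TERMS[case_label]
    model = ModelSpec(params=params)
    if term is None or magnitude == 0:
        # a zero-magnitude term is identically zero: the no-immigration model
        return model
    side, mode, sign = term
    spec = ImmigrationSpec(mode=mode, magnitude=magnitude, sign=sign)
    return model.with_prey(spec) if side == "prey" else model.with_pred(spec)


def _closed_form_point(
    params: LVParameters, case_label: str, magnitude: float
) -> Tuple[float, float, bool]:
    r, a, b, m = params.r, params.a, params.b, params.m
    c = d = magnitude
    if case_label == "classical":
        return m / b, r / a, True
    if case_label == "A1":
        return m / b, (m * r + b * c) / (a * m), True
    if case_label == "B1":
        return (m * r - a * d) / (b * r), r / a, m * r > a * d
    if case_label == "C1":
        return m / b, (m * m * r + b * b * c) / (a * m * m), True
    if case_label == "D1":
        return (m * r * r - a * a * d) / (b * r * r), r / a, m * r * r > a * a * d
    raise ValueError(f"unknown case label {case_label!r}")


def equilibrium_closed_form(
    params: LVParameters, case_label: str, magnitude: float = 0.0
) -> Equilibrium:
    """Evaluate the printed closed-form coexistence equilibrium for one case.

    Raises UnsupportedCaseError for saturating responses (h != 0 or alpha
    != 0); infeasible parameter combinations return ``feasible=False``
    rather than raising.
    """
    if params.h != 0 or params.alpha != 0:
        raise UnsupportedCaseError(
            "closed-form equilibria are defined for the linear response only "
            f"(h={params.h}, alpha={params.alpha})"
        )
    if case_label not in CLOSED_FORM_CASES:
        raise ValueError(f"unknown closed-form case {case_label!r}")
    x_star, y_star, feasible = _closed_form_point(params, case_label, magnitude)
    feasible = feasible and x_star > 0 and y_star > 0
    if feasible:
        model = model_for_case(params, case_label, magnitude)
        fx, fy = rhs_xy(x_star, y_star, model)
        residual = max(abs(fx), abs(fy))
    else:
        residual = math.nan
    return Equilibrium(x_star, y_star, case_label, feasible, residual)


def _baseline_guess(model: ModelSpec) -> Tuple[float, float]:
    """No-immigration coexistence root for the model's response type."""
    p = model.params
    if p.h == 0 and p.alpha == 0:
        return p.m / p.b, p.r / p.a
    # solve b*g(x) = m for the saturating responses: x^(1+alpha) = m/(b - h m)
    denom = p.b - p.h * p.m
    if denom <= 0:
        # predator cannot sustain itself at any prey density; start generic
        return 1.0, 1.0
    xp = p.m / denom
    x0 = xp ** (1.0 / (1.0 + p.alpha))
    # y from dx/dt = 0 without immigration: y = r*x/(a*g(x))
    y0 = p.r * (1.0 + p.h * xp) / (p.a * x0 ** p.alpha)
    return x0, y0


def _raw_field(model: ModelSpec):
    """Unguarded algebraic vector field for root-finding, so the solver can
    locate (and report) roots with a nonpositive coordinate."""
    return unguarded_field(model)


def equilibrium_numeric(
    model: ModelSpec,
    initial_guess: Optional[Tuple[float, float]] = None,
) -> Equilibrium:
    """Find a positive root of the vector field by damped Newton (hybr).

    Starts from the no-immigration baseline root (or the supplied guess) and
    retries with multiplicative perturbations {x1, x0.5, x2, x5} before
    declaring non-convergence.  A converged root with a nonpositive
    coordinate is reported as infeasible, not raised.
    """
    if not model.is_deterministic:
        raise ValueError("numeric equilibria are defined for deterministic models only")
    guess = initial_guess if initial_guess is not None else _baseline_guess(model)
    fun = _raw_field(model)
    best_nonpositive = None
    for factor in (1.0, 0.5, 2.0, 5.0):
        z0 = np.array([guess[0] * factor, guess[1] * factor])
        sol = optimize.root(fun, z0, method="hybr", tol=1e-14)
        # accept by certified residual, not solver status: hybr can flag
        # "not making progress" on an already-converged root
        residual = float(np.max(np.abs(fun(sol.x))))
        if residual > RESIDUAL_TOL:
            continue
        x_star, y_star = float(sol.x[0]), float(sol.x[1])
        # coordinates below the floor are axis roots, not coexistence
        if x_star > model.x_floor and y_star > model.x_floor:
            return Equilibrium(x_star, y_star, "numeric", True, residual)
        best_nonpositive = Equilibrium(x_star, y_star, "numeric", False, residual)
    if best_nonpositive is not None:
        return best_nonpositive
    raise NoConvergenceError(
        "root search failed to converge from the baseline guess and its "
        "retry ladder; supply an initial_guess"
    )
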