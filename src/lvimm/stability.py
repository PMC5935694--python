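"""Jacobian-based local stability analysis of coexistence equilibria.

The 2x2 Jacobian of the system at a point (x, y) is

    J11 = r - a*y*g'(x) + C'(x)        J12 = -a*g(x)
    J21 = b*y*g'(x)                    J22 = b*g(x) - m + D'(y)

with g'(x) = (1+alpha)*x^alpha / (1 + h*x^(1+alpha))^2, C' = 0 for the
constant mode and -sign*c/x^2 for the density-dependent mode (D' symmetric).

Classification follows the trace/determinant rule: the equilibrium is locally
asymptotically stable iff Tr(J) < 0 and Det(J) > 0.  The linear-response
cases with a single small immigration term admit closed-form amplitude decay
rates gamma (A1: b c/2m, B1: a d/2r, C1: b^2 c/m^2, D1: a^2 d/r^2), which
equal -Re(lambda) of the complex eigenvalue pair at the shifted equilibrium.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .equilibria import Equilibrium
from .model import (
    LVParameters,
    ModelSpec,
    State,
    functional_response_intake,
    functional_response_slope,
    immigration_slope,
)

__all__ = [
    "Classification",
    "StabilityReport",
    "jacobian_analytic",
    "classify",
    "gamma_closed_form",
    "beta_criterion",
    "NEUTRALITY_TOL",
]

NEUTRALITY_TOL = 1e-12


class Classification(str, enum.Enum):
    ASYMPTOTICALLY_STABLE = "asymptotically_stable"
    UNSTABLE = "unstable"
    NEUTRAL_CENTER = "neutral_center"
    SADDLE = "saddle"
    INFEASIBLE = "infeasible"

    @property
    def is_stable(self) -> bool:
        """Collapse to the stable / not-stable dichotomy."""
        return self is Classification.ASYMPTOTICALLY_STABLE


@dataclass(frozen=True)
class StabilityReport:
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    trace: float
    determinant: float
    classification: Classification
    gamma_analytic: Optional[float]
    gamma_numeric: float


def jacobian_analytic(model: ModelSpec, point: State) -> np.ndarray:
    """Analytic Jacobian of the deterministic vector field at a point."""
    if not model.is_deterministic:
        raise ValueError("the Jacobian is defined for deterministic models only")
    x, y = point.x, point.y
    if x <= 0 or y <= 0:
        raise ValueError(f"Jacobian requires x > 0 and y > 0, got ({x}, {y})")
    p = model.params
    g = functional_response_intake(x, p)
    gp = functional_response_slope(x, p)
    j11 = p.r - p.a * y * gp + immigration_slope(model.prey_imm, x)
    j12 = -p.a * g
    j21 = p.b * y * gp
    j22 = p.b * g - p.m + immigration_slope(model.pred_imm, y)
    return np.array([[j11, j12], [j21, j22]])


def gamma_closed_form(
    params: LVParameters, magnitude: float, case_label: str
) -> float:
    """Closed-form amplitude decay rate for the linear-response cases."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    r, a, b, m = params.r, params.a, params.b, params.m
    if case_label == "A1":
        return b * magnitude / (2.0 * m)
    if case_label == "B1":
        return a * magnitude / (2.0 * r)
    if case_label == "C1":
        return b * b * magnitude / (m * m)
    if case_label == "D1":
        return a * a * magnitude / (r * r)
    raise ValueError(f"no closed-form decay rate for case {case_label!r}")


def beta_criterion(params: LVParameters) -> float:
    """Stability criterion beta = r*b - h*m*r for the sigmoid response
    without immigration (positive beta implies local stability)."""
    return params.r * params.b - params.h * params.m * params.r


def _analytic_gamma_for(model: ModelSpec, case_label: str) -> Optional[float]:
    if case_label in ("A1", "C1"):
        return gamma_closed_form(model.params, model.prey_imm.magnitude, case_label)
    if case_label in ("B1", "D1"):
        return gamma_closed_form(model.params, model.pred_imm.magnitude, case_label)
    return None


def classify(
    model: ModelSpec, eq: Equilibrium, tol: float = NEUTRALITY_TOL
) -> StabilityReport:
    """Classify an equilibrium via trace/determinant with neutrality tolerance.

    Rules: infeasible equilibria short-circuit; Det < -tol -> saddle;
    |Tr| <= tol with Det > tol -> neutral_center; Tr < -tol with Det > tol
    -> asymptotically_stable; Tr > tol -> unstable.
    """
    if not eq.feasible:
        empty = np.full((2, 2), np.nan)
        return StabilityReport(
            jacobian=empty,
            eigenvalues=np.array([np.nan + 0j, np.nan + 0j]),
            trace=math.nan,
            determinant=math.nan,
            classification=Classification.INFEASIBLE,
            gamma_analytic=None,
            gamma_numeric=math.nan,
        )
    jac = jacobian_analytic(model, State(eq.x_star, eq.y_star))
    eigvals = np.linalg.eigvals(jac)
    trace = float(np.trace(jac))
    det = float(np.linalg.det(jac))
    if det < -tol:
        label = Classification.SADDLE
    elif abs(trace) <= tol and det > tol:
        label = Classification.NEUTRAL_CENTER
    elif trace < -tol and det > tol:
        label = Classification.ASYMPTOTICALLY_STABLE
    elif trace > tol:
        label = Classification.UNSTABLE
    else:
        # degenerate determinant: not certifiably stable
        label = Classification.UNSTABLE
    gamma_numeric = -float(np.max(eigvals.real))
    gamma_analytic = _analytic_gamma_for(model, eq.case_label)
    return StabilityReport(
        jacobian=jac,
        eigenvalues=eigvals,
        trace=trace,
        determinant=det,
        classification=label,
        gamma_analytic=gamma_analytic,
        gamma_numeric=gamma_numeric,
    )
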