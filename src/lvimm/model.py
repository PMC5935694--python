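"""Core predator-prey model: parameters, immigration terms, and the vector field.

The dynamical system is

    dx/dt = r*x - a*g(x)*y + C(x)
    dy/dt = b*g(x)*y - m*y + D(y)

with per-predator intake ``g(x) = x**(1+alpha) / (1 + h*x**(1+alpha))``.
``h = alpha = 0`` gives the classical linear (type I) response, ``h > 0,
alpha = 0`` the hyperbolic type II response, and ``h > 0, alpha > 0`` the
sigmoid type III response (``alpha = 1`` is the validated sigmoid case).

``C`` and ``D`` are small immigration (or, with negative sign, emigration)
terms: a constant rate, a density-dependent rate ``c/x``, or a piecewise
constant rate redrawn at regular intervals (``random_pulse``).
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Tuple

__all__ = [
    "ImmigrationMode",
    "LVParameters",
    "ImmigrationSpec",
    "ModelSpec",
    "State",
    "PositivityGuardError",
    "functional_response_intake",
    "functional_response_slope",
    "immigration_term",
    "immigration_slope",
    "rhs",
    "rhs_xy",
    "model_from_dict",
    "model_to_dict",
]

DEFAULT_FLOOR = 1e-6


class ImmigrationMode(str, enum.Enum):
    NONE = "none"
    CONSTANT = "constant"
    DENSITY_DEPENDENT = "density_dependent"
    RANDOM_PULSE = "random_pulse"


class PositivityGuardError(RuntimeError):
    """A density-dependent term was evaluated below the positivity floor."""

    def __init__(self, population: str, density: float, floor: float):
        self.population = population
        self.density = density
        self.floor = floor
        super().__init__(
            f"{population} density {density:g} fell below the positivity "
            f"floor {floor:g} while a density-dependent term is active"
        )


@dataclass(frozen=True)
class LVParameters:
    """Rate constants of the predator-prey system.

    r : prey reproduction rate (1/time)
    a : predation/consumption rate coefficient (1/(predator*time))
    b : predator birth rate per captured prey (1/(prey*time))
    m : predator mortality rate (1/time)
    h : functional-response saturation coefficient (default 0)
    alpha : Hill exponent (default 0); only {0, 1} are validated
    """

    r: float
    a: float
    b: float
    m: float
    h: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r", "a", "b", "m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.h < 0:
            raise ValueError(f"h must be >= 0, got {self.h}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")

    @property
    def response_type(self) -> str:
        """'I' (linear), 'II' (hyperbolic) or 'III' (sigmoid)."""
        if self.h == 0 and self.alpha == 0:
            return "I"
        if self.alpha == 0:
            return "II"
        return "III"

    @property
    def alpha_validated(self) -> bool:
        """Only alpha in {0, 1} is exercised by the validated surface."""
        return self.alpha in (0.0, 1.0)


@dataclass(frozen=True)
class ImmigrationSpec:
    """One population's inflow/outflow term.

    mode ``constant`` contributes ``sign*magnitude``; ``density_dependent``
    contributes ``sign*magnitude/density``; ``random_pulse`` contributes the
    currently drawn rate (always inflow). ``none`` contributes 0.
    """

    mode: ImmigrationMode = ImmigrationMode.NONE
    magnitude: float = 0.0
    sign: int = 1
    interval: Optional[float] = None
    low: Optional[float] = None
    high: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ImmigrationMode(self.mode))
        if self.sign not in (1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if self.magnitude < 0:
            raise ValueError(f"magnitude must be >= 0, got {self.magnitude}")
        if self.mode is ImmigrationMode.DENSITY_DEPENDENT and self.sign == 1:
            if not self.magnitude > 0:
                raise ValueError("density-dependent immigration requires magnitude > 0")
        if self.mode is ImmigrationMode.RANDOM_PULSE:
            if self.sign != 1:
                raise ValueError("random_pulse is inflow only (sign +1)")
            if self.low is None or self.high is None:
                raise ValueError("random_pulse requires low and high bounds")
            # low == high is allowed as a degenerate (constant-rate) draw
            if not (0 <= self.low <= self.high):
                raise ValueError(f"need 0 <= low <= high, got [{self.low}, {self.high}]")
            if self.interval is None or not self.interval > 0:
                raise ValueError("random_pulse requires interval > 0")

    # ---- convenience constructors -------------------------------------
    @classmethod
    def none(cls) -> "ImmigrationSpec":
        return cls(ImmigrationMode.NONE)

    @classmethod
    def constant(cls, magnitude: float, sign: int = 1) -> "ImmigrationSpec":
        return cls(ImmigrationMode.CONSTANT, magnitude=magnitude, sign=sign)

    @classmethod
    def density_dependent(cls, magnitude: float, sign: int = 1) -> "ImmigrationSpec":
        return cls(ImmigrationMode.DENSITY_DEPENDENT, magnitude=magnitude, sign=sign)

    @classmethod
    def random_pulse(cls, low: float, high: float, interval: float = 1.0) -> "ImmigrationSpec":
        return cls(ImmigrationMode.RANDOM_PULSE, low=low, high=high, interval=interval)

    @property
    def is_random(self) -> bool:
        return self.mode is ImmigrationMode.RANDOM_PULSE


@dataclass(frozen=True)
class ModelSpec:
    """Full dynamical system: rate constants plus both immigration sides."""

    params: LVParameters
    prey_imm: ImmigrationSpec = field(default_factory=ImmigrationSpec.none)
    pred_imm: ImmigrationSpec = field(default_factory=ImmigrationSpec.none)
    x_floor: float = DEFAULT_FLOOR

    def __post_init__(self) -> None:
        if not self.x_floor > 0:
            raise ValueError("x_floor must be > 0")

    @property
    def is_deterministic(self) -> bool:
        return not (self.prey_imm.is_random or self.pred_imm.is_random)

    def with_prey(self, spec: ImmigrationSpec) -> "ModelSpec":
        return replace(self, prey_imm=spec)

    def with_pred(self, spec: ImmigrationSpec) -> "ModelSpec":
        return replace(self, pred_imm=spec)


@dataclass
class State:
    """A point in phase space at time t (abundances are nonnegative)."""

    x: float
    y: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"abundances must be >= 0, got ({self.x}, {self.y})")


def functional_response_intake(x: float, params: LVParameters) -> float:
    """Per-predator capture factor g(x) = x^(1+alpha) / (1 + h*x^(1+alpha)).

    Reduces to g(x) = x for the linear (type I) response.
    """
    if x < 0:
        raise ValueError(f"prey abundance must be >= 0, got {x}")
    xp = x ** (1.0 + params.alpha)
    return xp / (1.0 + params.h * xp)


def functional_response_slope(x: float, params: LVParameters) -> float:
    """dg/dx = (1+alpha)*x^alpha / (1 + h*x^(1+alpha))^2."""
    if x < 0:
        raise ValueError(f"prey abundance must be >= 0, got {x}")
    denom = 1.0 + params.h * x ** (1.0 + params.alpha)
    return (1.0 + params.alpha) * x ** params.alpha / (denom * denom)


def immigration_term(
    spec: ImmigrationSpec,
    density: float,
    current_draw: Optional[float] = None,
    *,
    floor: float = DEFAULT_FLOOR,
    population: str = "population",
) -> float:
    """Rate contribution of one immigration side at the given density."""
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    mode = spec.mode
    if mode is ImmigrationMode.NONE:
        return 0.0
    if mode is ImmigrationMode.CONSTANT:
        return spec.sign * spec.magnitude
    if mode is ImmigrationMode.DENSITY_DEPENDENT:
        if density < floor:
            raise PositivityGuardError(population, density, floor)
        return spec.sign * spec.magnitude / density
    # random_pulse: the active draw is the rate
    if current_draw is None:
        raise ValueError("random_pulse mode requires the active drawn rate")
    return current_draw


def immigration_slope(spec: ImmigrationSpec, density: float) -> float:
    """Derivative of the immigration term with respect to its own density."""
    if spec.mode is ImmigrationMode.DENSITY_DEPENDENT:
        return -spec.sign * spec.magnitude / (density * density)
    return 0.0


def rhs(
    state: State,
    model: ModelSpec,
    draws: Optional[Tuple[Optional[float], Optional[float]]] = None,
) -> Tuple[float, float]:
    """Vector field (dx/dt, dy/dt) at the given state."""
    c_draw, d_draw = draws if draws is not None else (None, None)
    return rhs_xy(state.x, state.y, model, c_draw=c_draw, d_draw=d_draw)


def rhs_xy(
    x: float,
    y: float,
    model: ModelSpec,
    c_draw: Optional[float] = None,
    d_draw: Optional[float] = None,
) -> Tuple[float, float]:
    """Vector field on raw coordinates (used by the integrator and solvers)."""
    p = model.params
    g = functional_response_intake(x, p)
    cx = immigration_term(model.prey_imm, x, c_draw, floor=model.x_floor, population="prey")
    dy_term = immigration_term(model.pred_imm, y, d_draw, floor=model.x_floor, population="predator")
    dxdt = p.r * x - p.a * g * y + cx
    dydt = p.b * g * y - p.m * y + dy_term
    return dxdt, dydt


def unguarded_field(model: ModelSpec, c_draw=None, d_draw=None):
    """Raw algebraic vector field without positivity guards.

    Internal helper for root-finding and for the integrator, whose trial
    steps (and the event localization bracketing a floor crossing) may probe
    states slightly outside the guarded domain.  Densities are kept away
    from zero where they appear in a denominator; a negative prey abundance
    is handled through the odd extension of x^(1+alpha).
    """
    import numpy as np

    p = model.params
    tiny = 1e-12
    expo = 1.0 + p.alpha

    def _imm(spec: ImmigrationSpec, density: float, draw) -> float:
        if spec.mode is ImmigrationMode.CONSTANT:
            return spec.sign * spec.magnitude
        if spec.mode is ImmigrationMode.DENSITY_DEPENDENT:
            if abs(density) < tiny:
                density = math.copysign(tiny, density if density != 0 else 1.0)
            return spec.sign * spec.magnitude / density
        if spec.mode is ImmigrationMode.RANDOM_PULSE:
            return draw if draw is not None else 0.0
        return 0.0

    def fun(z):
        x, y = float(z[0]), float(z[1])
        xp = math.copysign(abs(x) ** expo, x) if x < 0 else x ** expo
        g = xp / (1.0 + p.h * xp)
        fx = p.r * x - p.a * g * y + _imm(model.prey_imm, x, c_draw)
        fy = p.b * g * y - p.m * y + _imm(model.pred_imm, y, d_draw)
        return np.array([fx, fy])

    return fun


# ---------------------------------------------------------------------------
# Flat config serialization
# ---------------------------------------------------------------------------

_MODE_KEYS = {"prey": ("prey_mode", "prey_c", "prey_sign"), "pred": ("pred_mode", "pred_d", "pred_sign")}


def _imm_from_flat(cfg: Mapping, side: str) -> ImmigrationSpec:
    mode_key, mag_key, sign_key = _MODE_KEYS[side]
    mode = ImmigrationMode(cfg.get(mode_key, "none"))
    if mode is ImmigrationMode.RANDOM_PULSE:
        return ImmigrationSpec.random_pulse(
            low=float(cfg.get("low", 0.0)),
            high=float(cfg.get("high", 1.0)),
            interval=float(cfg.get("interval", 1.0)),
        )
    return ImmigrationSpec(
        mode=mode,
        magnitude=float(cfg.get(mag_key, 0.0)),
        sign=int(cfg.get(sign_key, 1)),
    )


def model_from_dict(cfg: Mapping) -> ModelSpec:
    """Build a ModelSpec from a flat config mapping.

    Recognized keys: r, a, b, m, h, alpha, prey_mode, prey_c, prey_sign,
    pred_mode, pred_d, pred_sign, interval, low, high, x_floor.  Extra keys
    (x0, y0, ...) are ignored so the same file can carry run settings.
    """
    params = LVParameters(
        r=float(cfg["r"]),
        a=float(cfg["a"]),
        b=float(cfg["b"]),
        m=float(cfg["m"]),
        h=float(cfg.get("h", 0.0)),
        alpha=float(cfg.get("alpha", 0.0)),
    )
    return ModelSpec(
        params=params,
        prey_imm=_imm_from_flat(cfg, "prey"),
        pred_imm=_imm_from_flat(cfg, "pred"),
        x_floor=float(cfg.get("x_floor", DEFAULT_FLOOR)),
    )


def model_to_dict(model: ModelSpec) -> dict:
    """Flatten a ModelSpec to the config key set accepted by model_from_dict."""
    p = model.params
    out = {
        "r": p.r, "a": p.a, "b": p.b, "m": p.m, "h": p.h, "alpha": p.alpha,
        "prey_mode": model.prey_imm.mode.value,
        "prey_c": model.prey_imm.magnitude,
        "prey_sign": model.prey_imm.sign,
        "pred_mode": model.pred_imm.mode.value,
        "pred_d": model.pred_imm.magnitude,
        "pred_sign": model.pred_imm.sign,
        "x_floor": model.x_floor,
    }
    for imm in (model.prey_imm, model.pred_imm):
        if imm.is_random:
            out.update(interval=imm.interval, low=imm.low, high=imm.high)
    return out
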