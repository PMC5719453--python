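"""Core eco-evolutionary predator-prey model.

A single prey population (biomass ``x``) with an evolving defense trait
``u`` interacts with a single predator population (biomass ``y``) carrying
an evolving offense trait ``v``.  Prey grow logistically and are consumed
through a Holling type II functional response whose attack rate depends on
the trait difference ``u - v`` (a unidirectional trait axis: defense lowers
capture success, offense restores it).  Defense trades off against the
intrinsic growth rate, offense against the conversion efficiency.  Both
traits evolve by quantitative genetics: the trait velocity is the additive
genetic variance times the fitness gradient, damped by a smooth boundary
factor that keeps traits positive.

All functions here are pure and accept either scalars or numpy arrays for
the state arguments; parameters are carried by :class:`ModelParams` and
:class:`AdaptationParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

__all__ = [
    "EXP_CLAMP",
    "TradeOff",
    "GaussianTradeOff",
    "ModelParams",
    "AdaptationParams",
    "SystemState",
    "attack_rate",
    "attack_rate_trait_derivative",
    "prey_growth_tradeoff",
    "conversion_tradeoff",
    "prey_fitness",
    "predator_fitness",
    "fitness_gradients",
    "fitness_partials",
    "system_derivatives",
]

# Exponent clamp for the logistic attack rate: beyond +/-700 the double
# overflows; clamping keeps a(u, v) finite and monotone (it saturates).
EXP_CLAMP = 700.0


class TradeOff(Protocol):
    """Narrow interface for a trait cost function: value and derivative.

    ``value(z)`` is the realized rate (growth rate or conversion
    efficiency) at trait level ``z >= 0``; ``derivative(z)`` is its
    derivative with respect to the trait.
    """

    def value(self, z): ...

    def derivative(self, z): ...


@dataclass(frozen=True)
class GaussianTradeOff:
    """Gaussian-decay trade-off ``maximum * exp(-cost * z**2)``.

    The default cost shape for both trophic levels: cost-free at zero trait
    investment, with the decay rate set by the costliness parameter.
    """

    maximum: float
    cost: float

    def value(self, z):
        return self.maximum * np.exp(-self.cost * np.square(z))

    def derivative(self, z):
        return -2.0 * self.cost * z * self.value(z)


@dataclass(frozen=True)
class ModelParams:
    """Ecological and trade-off constants.

    Parameters
    ----------
    r0 : maximum prey growth rate (1/time)
    K : prey carrying capacity (biomass)
    a0 : maximum attack rate (1/(biomass*time))
    h : handling time (time)
    theta : steepness of the attack-rate transition in the trait difference
    g0 : maximum conversion efficiency (dimensionless)
    d : predator per-capita mortality (1/time)
    cx : costliness of defense
    cy : costliness of offense
    growth_tradeoff, conversion_tradeoff : optional overrides of the
        default Gaussian trade-offs (any object with ``value``/``derivative``).
    """

    r0: float = 1.0
    K: float = 1.0
    a0: float = 1.0
    h: float = 0.1
    theta: float = 10.0
    g0: float = 1.0
    d: float = 0.1
    cx: float = 3.0
    cy: float = 2.0
    growth_tradeoff: TradeOff | None = field(default=None, compare=False)
    conversion_tradeoff: TradeOff | None = field(default=None, compare=False)

    def __post_init__(self):
        for name in ("r0", "K", "a0", "theta", "g0", "d"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("h", "cx", "cy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.growth_tradeoff is None:
            object.__setattr__(
                self, "growth_tradeoff", GaussianTradeOff(self.r0, self.cx)
            )
        if self.conversion_tradeoff is None:
            object.__setattr__(
                self, "conversion_tradeoff", GaussianTradeOff(self.g0, self.cy)
            )


@dataclass(frozen=True)
class AdaptationParams:
    """Evolutionary speed constants.

    ``Gx`` and ``Gy`` are the additive genetic variances of prey and
    predator; they set the speed of trait change relative to the ecological
    dynamics (1 means equally fast).  ``eps`` is the boundary constant of
    the smooth factor ``exp(-eps/trait)`` that stalls evolution as a trait
    approaches zero, keeping traits positive.
    """

    Gx: float = 1e-2
    Gy: float = 1e-2
    eps: float = 1e-3

    def __post_init__(self):
        if self.Gx < 0 or self.Gy < 0:
            raise ValueError("Gx and Gy must be nonnegative")
        if not self.eps > 0:
            raise ValueError("eps must be strictly positive")


@dataclass(frozen=True)
class SystemState:
    """State of the 4-variable system: biomasses ``x, y``; traits ``u, v``."""

    x: float
    y: float
    u: float
    v: float

    def __post_init__(self):
        if self.x < 0 or self.y < 0:
            raise ValueError("biomasses must be nonnegative")
        if self.u < 0 or self.v < 0:
            raise ValueError("traits must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.u, self.v])


# ----------------------------------------------------------------------
# Ecological rates and trade-offs
# ----------------------------------------------------------------------

def attack_rate(u, v, p: ModelParams):
    """Attack rate ``a0 / (1 + exp(theta*(u - v)))``.

    Strictly decreasing in defense ``u`` and increasing in offense ``v``;
    saturates at ``a0`` for ``v >> u`` and at 0 for ``u >> v``.  The
    exponent is clamped to avoid overflow, so the result is always finite.
    """
    z = np.clip(p.theta * (np.asarray(u) - v), -EXP_CLAMP, EXP_CLAMP)
    out = p.a0 / (1.0 + np.exp(z))
    return float(out) if np.ndim(out) == 0 else out


def attack_rate_trait_derivative(u, v, p: ModelParams):
    """Derivative of the attack rate with respect to defense ``u``.

    Equals ``-theta * a * (1 - a/a0)``; the derivative with respect to
    offense ``v`` is its negative (the rate depends on ``u - v`` only).
    """
    a = attack_rate(u, v, p)
    return -p.theta * a * (1.0 - a / p.a0)


def prey_growth_tradeoff(u, p: ModelParams):
    """Realized prey growth rate ``r(u)``; maximal at zero defense."""
    return p.growth_tradeoff.value(u)


def conversion_tradeoff(v, p: ModelParams):
    """Realized conversion efficiency ``g(v)``; maximal at zero offense."""
    return p.conversion_tradeoff.value(v)


# ----------------------------------------------------------------------
# Fitness (per-capita net growth rates)
# ----------------------------------------------------------------------

def prey_fitness(x, y, u, v, p: ModelParams):
    """Prey Malthusian fitness W_x = r(u)(1 - x/K) - a*y / (1 + a*h*x)."""
    a = attack_rate(u, v, p)
    return prey_growth_tradeoff(u, p) * (1.0 - np.asarray(x) / p.K) - a * y / (
        1.0 + a * p.h * np.asarray(x)
    )


def predator_fitness(x, y, u, v, p: ModelParams):
    """Predator Malthusian fitness W_y = g(v)*a*x/(1 + a*h*x) - d.

    Independent of predator biomass ``y`` (the argument is accepted for a
    uniform signature); this is what makes the predator's own-biomass
    Geber component identically zero.
    """
    del y
    a = attack_rate(u, v, p)
    return (
        conversion_tradeoff(v, p) * a * np.asarray(x) / (1.0 + a * p.h * np.asarray(x))
        - p.d
    )


# ----------------------------------------------------------------------
# Analytic partial derivatives
# ----------------------------------------------------------------------

def fitness_partials(x, y, u, v, p: ModelParams):
    """All analytic partials of (W_x, W_y) with respect to (x, y, u, v).

    Returns a dict with keys ``dWx_dx, dWx_dy, dWx_du, dWx_dv, dWy_dx,
    dWy_dy, dWy_du, dWy_dv``.  These are the exact derivatives of the
    fitness expressions; the Geber decomposition multiplies each by the
    model time-derivative of its variable.
    """
    x = np.asarray(x, dtype=float)
    a = attack_rate(u, v, p)
    a_u = attack_rate_trait_derivative(u, v, p)  # da/du; da/dv = -a_u
    g = conversion_tradeoff(v, p)
    denom = 1.0 + a * p.h * x
    denom2 = denom * denom
    r_prime = p.growth_tradeoff.derivative(u)
    g_prime = p.conversion_tradeoff.derivative(v)

    return {
        # prey fitness
        "dWx_dx": -prey_growth_tradeoff(u, p) / p.K + a * a * p.h * y / denom2,
        "dWx_dy": -a / denom,
        "dWx_du": r_prime * (1.0 - x / p.K) - y * a_u / denom2,
        "dWx_dv": -y * (-a_u) / denom2,
        # predator fitness
        "dWy_dx": g * a / denom2,
        "dWy_dy": np.zeros_like(x * 1.0) if np.ndim(x) else 0.0,
        "dWy_du": g * x * a_u / denom2,
        "dWy_dv": g_prime * a * x / denom + g * x * (-a_u) / denom2,
    }


def fitness_gradients(x, y, u, v, p: ModelParams):
    """Selection gradients (dW_x/du, dW_y/dv) driving trait evolution."""
    parts = fitness_partials(x, y, u, v, p)
    return parts["dWx_du"], parts["dWy_dv"]


# ----------------------------------------------------------------------
# Coupled right-hand side
# ----------------------------------------------------------------------

def _boundary(trait, eps):
    """Smooth positivity boundary exp(-eps/trait); 0 at and below zero."""
    trait = np.asarray(trait, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        out = np.where(trait > 0.0, np.exp(-eps / np.maximum(trait, 1e-300)), 0.0)
    return float(out) if np.ndim(out) == 0 else out


def system_derivatives(x, y, u, v, p: ModelParams, a: AdaptationParams):
    """Time derivatives (dx/dt, dy/dt, du/dt, dv/dt) of the full system.

    Biomasses follow fitness times biomass; traits follow the fitness
    gradient scaled by the genetic variance and the positivity boundary
    factor ``exp(-eps/trait)``.
    """
    if np.any(np.asarray(u) < 0) or np.any(np.asarray(v) < 0):
        raise ValueError("traits must be nonnegative")
    wx = prey_fitness(x, y, u, v, p)
    wy = predator_fitness(x, y, u, v, p)
    grad_u, grad_v = fitness_gradients(x, y, u, v, p)
    dx = wx * np.asarray(x)
    dy = wy * np.asarray(y)
    du = a.Gx * grad_u * _boundary(u, a.eps)
    dv = a.Gy * grad_v * _boundary(v, a.eps)
    return dx, dy, du, dv


def make_rhs(p: ModelParams, a: AdaptationParams):
    """Build a fast scalar right-hand side ``f(t, [x,y,u,v])`` for the ODE solver.

    Inlines the default Gaussian trade-offs when present; falls back to the
    pluggable hooks otherwise.  Scalar ``math`` code keeps per-call cost low
    inside adaptive integration.
    """
    import math

    r0, K, a0, h, theta, g0, d = p.r0, p.K, p.a0, p.h, p.theta, p.g0, p.d
    cx, cy = p.cx, p.cy
    Gx, Gy, eps = a.Gx, a.Gy, a.eps
    gauss_r = isinstance(p.growth_tradeoff, GaussianTradeOff) and (
        p.growth_tradeoff == GaussianTradeOff(r0, cx)
    )
    gauss_g = isinstance(p.conversion_tradeoff, GaussianTradeOff) and (
        p.conversion_tradeoff == GaussianTradeOff(g0, cy)
    )
    r_val = p.growth_tradeoff.value
    r_der = p.growth_tradeoff.derivative
    g_val = p.conversion_tradeoff.value
    g_der = p.conversion_tradeoff.derivative
    exp = math.exp

    def rhs(t, state):
        x, y, u, v = state
        z = theta * (u - v)
        if z > EXP_CLAMP:
            z = EXP_CLAMP
        elif z < -EXP_CLAMP:
            z = -EXP_CLAMP
        ez = exp(z)
        a_ = a0 / (1.0 + ez)
        a_u = -theta * a_ * (1.0 - a_ / a0)
        if gauss_r:
            r = r0 * exp(-cx * u * u)
            rp = -2.0 * cx * u * r
        else:
            r = r_val(u)
            rp = r_der(u)
        if gauss_g:
            g = g0 * exp(-cy * v * v)
            gp = -2.0 * cy * v * g
        else:
            g = g_val(v)
            gp = g_der(v)
        denom = 1.0 + a_ * h * x
        denom2 = denom * denom
        wx = r * (1.0 - x / K) - a_ * y / denom
        wy = g * a_ * x / denom - d
        grad_u = rp * (1.0 - x / K) - y * a_u / denom2
        grad_v = gp * a_ * x / denom + g * x * (-a_u) / denom2
        bu = exp(-eps / u) if u > 0.0 else 0.0
        bv = exp(-eps / v) if v > 0.0 else 0.0
        return (wx * x, wy * y, Gx * grad_u * bu, Gy * grad_v * bv)

    return rhs
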