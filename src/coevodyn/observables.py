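"""Derived observables along a trajectory.

Two observables carry the analysis:

* the **effective prey biomass** — prey biomass as perceived by the
  predator, i.e. weighted by the relative attack rate and relative
  conversion efficiency;

* the **Geber decomposition** of fitness change — the time derivative of
  each trophic level's Malthusian fitness split, by the multivariate chain
  rule, into the additive contributions of the four changing state
  variables (prey biomass, predator biomass, defense, offense).  Each
  component is an analytic partial derivative of the fitness times the
  analytic model time-derivative of that variable, so the components sum
  to dW/dt exactly (up to solver error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    ModelParams,
    attack_rate,
    conversion_tradeoff,
    fitness_partials,
    system_derivatives,
)
from .simulation import Trajectory

__all__ = [
    "PREY_COMPONENTS",
    "PREDATOR_COMPONENTS",
    "COMPONENT_NAMES",
    "ComponentSeries",
    "EffectiveBiomassSeries",
    "effective_prey_biomass",
    "effective_biomass_series",
    "geber_components",
    "standardize_components",
]

PREY_COMPONENTS = ("Ex_x", "Ey_x", "Eu_x", "Ev_x")
PREDATOR_COMPONENTS = ("Ex_y", "Ey_y", "Eu_y", "Ev_y")
COMPONENT_NAMES = PREY_COMPONENTS + PREDATOR_COMPONENTS


@dataclass(frozen=True)
class ComponentSeries:
    """The eight Geber component time series aligned to a trajectory.

    Naming: ``E<var>_<level>`` is the effect of the change in ``var`` on
    the fitness of ``level`` — e.g. ``Eu_y`` is the effect of defense on
    the predator.  Units are fitness change per time (1/time^2).
    ``Ey_y`` is identically zero because predator fitness does not depend
    on predator biomass.
    """

    times: np.ndarray
    Ex_x: np.ndarray
    Ey_x: np.ndarray
    Eu_x: np.ndarray
    Ev_x: np.ndarray
    Ex_y: np.ndarray
    Ey_y: np.ndarray
    Eu_y: np.ndarray
    Ev_y: np.ndarray

    def component(self, name: str) -> np.ndarray:
        if name not in COMPONENT_NAMES:
            raise KeyError(f"unknown component {name!r}")
        return getattr(self, name)

    def window(self, t_start: float, t_stop: float | None = None) -> "ComponentSeries":
        if t_stop is None:
            t_stop = self.times[-1]
        mask = (self.times >= t_start - 1e-9) & (self.times <= t_stop + 1e-9)
        return ComponentSeries(
            self.times[mask],
            *(self.component(name)[mask] for name in COMPONENT_NAMES),
        )

    def prey_sum(self) -> np.ndarray:
        """Sum of the four prey components = dW_x/dt."""
        return self.Ex_x + self.Ey_x + self.Eu_x + self.Ev_x

    def predator_sum(self) -> np.ndarray:
        """Sum of the four predator components = dW_y/dt."""
        return self.Ex_y + self.Ey_y + self.Eu_y + self.Ev_y


@dataclass(frozen=True)
class EffectiveBiomassSeries:
    """Effective prey biomass x_eff along a trajectory; 0 <= x_eff <= x."""

    times: np.ndarray
    x_eff: np.ndarray


def effective_prey_biomass(x, u, v, p: ModelParams):
    """Effective prey biomass x_eff = x * (a(u,v)/a0) * (g(v)/g0).

    Prey biomass discounted by how catchable (relative attack rate) and
    how digestible/profitable (relative conversion efficiency) the prey
    currently is to the predator.
    """
    return (
        np.asarray(x)
        * (attack_rate(u, v, p) / p.a0)
        * (conversion_tradeoff(v, p) / p.g0)
    )


def effective_biomass_series(traj: Trajectory) -> EffectiveBiomassSeries:
    """Evaluate the effective prey biomass at every trajectory sample."""
    return EffectiveBiomassSeries(
        traj.times, effective_prey_biomass(traj.x, traj.u, traj.v, traj.params)
    )


def geber_components(traj: Trajectory) -> ComponentSeries:
    """Geber decomposition of dW_x/dt and dW_y/dt along a trajectory.

    Each component is (analytic partial of the fitness with respect to one
    variable) x (that variable's model time-derivative), evaluated at every
    sample.  No numerical differentiation is involved, so the chain-rule
    identity sum(components) = dW/dt holds exactly.
    """
    x, y, u, v = traj.x, traj.y, traj.u, traj.v
    parts = fitness_partials(x, y, u, v, traj.params)
    dx, dy, du, dv = system_derivatives(x, y, u, v, traj.params, traj.adaptation)
    return ComponentSeries(
        times=traj.times,
        Ex_x=parts["dWx_dx"] * dx,
        Ey_x=parts["dWx_dy"] * dy,
        Eu_x=parts["dWx_du"] * du,
        Ev_x=parts["dWx_dv"] * dv,
        Ex_y=parts["dWy_dx"] * dx,
        Ey_y=parts["dWy_dy"] * dy,
        Eu_y=parts["dWy_du"] * du,
        Ev_y=parts["dWy_dv"] * dv,
    )


def standardize_components(cs: ComponentSeries) -> ComponentSeries:
    """Scale each component by its own maximum absolute value.

    After standardization every nonzero component ranges within [-1, 1]
    and attains magnitude 1 somewhere; identically-zero components (e.g.
    the predator's own-biomass effect) are left untouched.  Intended for
    plotting on a common axis.
    """
    scaled = {}
    for name in COMPONENT_NAMES:
        series = cs.component(name)
        peak = np.max(np.abs(series)) if series.size else 0.0
        scaled[name] = series / peak if peak > 0 else series.copy()
    return ComponentSeries(cs.times, *(scaled[name] for name in COMPONENT_NAMES))
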