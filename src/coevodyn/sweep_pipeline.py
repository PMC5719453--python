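"""Parameter-grid sweeps and phase/correlation association analysis.

A *set* is one grid of simulations over two focal parameters (speed
analysis: the genetic variances Gx, Gy; cost analysis: the costliness
parameters cx, cy) with everything else fixed.  Every cell is simulated,
classified, and — when it cycles — phase- and correlation-analyzed.  Per
set, the association r_A is the Spearman correlation, across cycling
cells, between the predator-prey phase lag phi and one component
correlation r_C; sets that do not contain both antiphase and quarter-lag
cells are excluded.  Associations are finally averaged over the included
sets of a family.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
from joblib import Parallel, delayed
from scipy.stats import spearmanr

from .core_model import AdaptationParams, ModelParams
from .correlation_analysis import (
    COMPONENT_PAIRS,
    component_correlations,
    pair_name,
)
from .observables import geber_components
from .phase_analysis import PhaseUndefinedError, all_phase_relationships
from .simulation import IntegrationError, SimConfig, classify_outcome, integrate

__all__ = [
    "GridSpec",
    "CellResult",
    "SweepSet",
    "AssociationTable",
    "speed_grid",
    "cost_grid",
    "run_cell",
    "run_set",
    "set_association",
    "aggregate_associations",
    "speed_family_fixed",
    "cost_family_fixed",
]

logger = logging.getLogger(__name__)

PAIR_NAMES = tuple(pair_name(p) for p in COMPONENT_PAIRS)

#: Minimum number of usable cells for a set's associations to be defined.
MIN_USABLE_CELLS = 3

#: Fields that live on AdaptationParams rather than ModelParams.
_ADAPTATION_FIELDS = frozenset({"Gx", "Gy", "eps"})


@dataclass(frozen=True)
class GridSpec:
    """Two focal-parameter axes: names and the values along each."""

    axis_names: tuple[str, str]
    values1: np.ndarray
    values2: np.ndarray


def speed_grid(n: int = 25, low: float = 10**-2.5, high: float = 1.0) -> GridSpec:
    """Log-spaced grid over the adaptation speeds Gx, Gy."""
    vals = np.logspace(np.log10(low), np.log10(high), n)
    return GridSpec(("Gx", "Gy"), vals, vals.copy())


def cost_grid(n: int = 25, low: float = 0.0, high: float = 10.0) -> GridSpec:
    """Linearly spaced grid over the costliness parameters cx, cy."""
    vals = np.linspace(low, high, n)
    return GridSpec(("cx", "cy"), vals, vals.copy())


@dataclass(frozen=True)
class CellResult:
    """Record of one grid cell: focal values, outcome, phases, correlations."""

    values: tuple[float, float]
    outcome: str | None
    phases: dict[str, float] | None
    phase_label: str | None
    period: float | None
    rC: dict[str, float] | None
    error: str | None = None


@dataclass(frozen=True)
class SweepSet:
    """One fully computed grid ('set') of simulations."""

    grid: GridSpec
    fixed_model: ModelParams
    fixed_adaptation: AdaptationParams
    config: SimConfig
    cells: list[CellResult]

    def cell_grid(self) -> np.ndarray:
        """Cells reshaped to (len(values1), len(values2))."""
        n1, n2 = len(self.grid.values1), len(self.grid.values2)
        return np.array(self.cells, dtype=object).reshape(n1, n2)


@dataclass(frozen=True)
class AssociationTable:
    """Per-set associations r_A and their aggregate over included sets."""

    per_set: list[dict[str, float] | None]
    included: list[bool]
    aggregate: dict[str, dict[str, float]]  # pair -> {mean, sd, n_sets}


def _apply_overrides(
    p: ModelParams, a: AdaptationParams, overrides: dict[str, float]
) -> tuple[ModelParams, AdaptationParams]:
    model_kwargs = {k: v for k, v in overrides.items() if k not in _ADAPTATION_FIELDS}
    adapt_kwargs = {k: v for k, v in overrides.items() if k in _ADAPTATION_FIELDS}
    if model_kwargs:
        # rebuild so default trade-offs pick up new r0/cx/g0/cy
        p = replace(p, growth_tradeoff=None, conversion_tradeoff=None, **model_kwargs)
    if adapt_kwargs:
        a = replace(a, **adapt_kwargs)
    return p, a


def run_cell(
    p: ModelParams, a: AdaptationParams, cfg: SimConfig, values: tuple[float, float]
) -> CellResult:
    """Simulate and analyze one parameter combination.

    Failures (solver breakdown, undefined phase on a non-cycling run) are
    captured in the record, never raised, so a sweep survives bad cells.
    """
    try:
        traj = integrate(p, a, cfg)
        outcome = classify_outcome(traj, cfg)
        if outcome.label != "cycles":
            return CellResult(values, outcome.label, None, None, None, None)
        phases = all_phase_relationships(traj)
        corr = component_correlations(geber_components(traj).window(cfg.t_transient))
        return CellResult(
            values=values,
            outcome=outcome.label,
            phases={k: pr.phi for k, pr in phases.items()},
            phase_label=phases["phi_xy"].label,
            period=phases["phi_xy"].period,
            rC=corr.rC,
        )
    except (IntegrationError, PhaseUndefinedError) as exc:
        logger.warning("cell %s failed: %s", values, exc)
        return CellResult(values, None, None, None, None, None, error=str(exc))


def run_set(
    grid: GridSpec,
    fixed_model: ModelParams,
    fixed_adaptation: AdaptationParams,
    cfg: SimConfig | None = None,
    n_jobs: int = 1,
) -> SweepSet:
    """Run every cell of a grid; cells are independent and order-invariant."""
    cfg = cfg or SimConfig()
    combos = list(itertools.product(grid.values1, grid.values2))
    logger.info(
        "running set over %s x %s: %d cells",
        grid.axis_names[0],
        grid.axis_names[1],
        len(combos),
    )

    def one(v1: float, v2: float) -> CellResult:
        p, a = _apply_overrides(
            fixed_model, fixed_adaptation, dict(zip(grid.axis_names, (v1, v2)))
        )
        result = run_cell(p, a, cfg, (float(v1), float(v2)))
        logger.info(
            "cell %s=%g %s=%g -> %s",
            grid.axis_names[0], v1, grid.axis_names[1], v2,
            result.outcome or f"error: {result.error}",
        )
        return result

    if n_jobs == 1:
        cells = [one(v1, v2) for v1, v2 in combos]
    else:
        cells = Parallel(n_jobs=n_jobs)(delayed(one)(v1, v2) for v1, v2 in combos)
    return SweepSet(grid, fixed_model, fixed_adaptation, cfg, cells)


def set_association(s: SweepSet) -> tuple[dict[str, float] | None, bool]:
    """Associations r_A of one set, plus its inclusion flag.

    r_A for a pair is the Spearman correlation between phi(x->y) and that
    pair's r_C across the cycling cells where both are defined.  The set
    is included only if its cycling cells contain both an antiphase and a
    quarter-lag cell and at least ``MIN_USABLE_CELLS`` cells are usable.
    """
    cycling = [c for c in s.cells if c.outcome == "cycles" and c.phases is not None]
    labels = {c.phase_label for c in cycling}
    has_both = "antiphase" in labels and "quarter_lag" in labels
    if len(cycling) < MIN_USABLE_CELLS:
        return None, False
    rA: dict[str, float] = {}
    for name in PAIR_NAMES:
        phis, rcs = [], []
        for c in cycling:
            rc = c.rC.get(name, float("nan"))
            if np.isfinite(rc):
                phis.append(c.phases["phi_xy"])
                rcs.append(rc)
        if len(phis) < MIN_USABLE_CELLS or np.ptp(phis) == 0 or np.ptp(rcs) == 0:
            # undefined with too few cells or a constant input
            rA[name] = float("nan")
        else:
            rA[name] = float(spearmanr(phis, rcs).statistic)
    return rA, has_both


def aggregate_associations(sets: list[SweepSet]) -> AssociationTable:
    """Mean and standard deviation of each r_A across included sets."""
    per_set: list[dict[str, float] | None] = []
    included: list[bool] = []
    for s in sets:
        rA, ok = set_association(s)
        per_set.append(rA)
        included.append(ok and rA is not None)
    aggregate: dict[str, dict[str, float]] = {}
    for name in PAIR_NAMES:
        vals = [
            rA[name]
            for rA, ok in zip(per_set, included)
            if ok and np.isfinite(rA[name])
        ]
        if vals:
            aggregate[name] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals)),
                "n_sets": len(vals),
            }
        else:
            aggregate[name] = {"mean": float("nan"), "sd": float("nan"), "n_sets": 0}
    return AssociationTable(per_set, included, aggregate)


def speed_family_fixed(
    K_values=(1.0, 1.5, 2.0),
    h_values=(0.1, 1.0),
    cx_values=(2.0, 3.0, 4.0, 5.0),
    cy_values=(2.0, 3.0, 4.0, 5.0),
) -> list[tuple[ModelParams, AdaptationParams]]:
    """Fixed-parameter combinations of the speed-analysis family.

    The focal grid runs over (Gx, Gy); each crossing of carrying capacity,
    handling time and the two costliness values yields one set.
    """
    return [
        (ModelParams(K=K, h=h, cx=cx, cy=cy), AdaptationParams())
        for K, h, cx, cy in itertools.product(K_values, h_values, cx_values, cy_values)
    ]


def cost_family_fixed(
    K_values=(1.0, 1.5, 2.0),
    a0_values=(0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0),
    h_values=(1.0, 1.5, 2.0),
    Gx_values=(1e-2, 10**-1.5),
    Gy: float = 1e-2,
) -> list[tuple[ModelParams, AdaptationParams]]:
    """Fixed-parameter combinations of the cost-analysis family.

    The focal grid runs over (cx, cy); the predator's adaptation speed is
    held at its standard value.
    """
    return [
        (ModelParams(K=K, a0=a0, h=h), AdaptationParams(Gx=Gx, Gy=Gy))
        for K, a0, h, Gx in itertools.product(K_values, a0_values, h_values, Gx_values)
    ]
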