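"""Component correlations within one simulation.

For each cycling run, Spearman rank correlations (r_C) are computed
between pairs of Geber component series over the last 5,000 time units.
Of the 12 possible pairs only 8 are admissible: the prey-biomass vs
predator-biomass pairs merely restate the predator-prey phase
relationship, and every pair involving the predator's own-biomass effect
is degenerate because that component is identically zero.  Rank
correlation makes the result invariant to any strictly monotone rescaling
of the components, so raw (unstandardized) series are used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .observables import ComponentSeries
from .simulation import CORRELATION_WINDOW

__all__ = ["COMPONENT_PAIRS", "CorrelationSet", "component_correlations"]

#: The 8 admissible component pairs: 5 on the prey side, 3 on the predator side.
COMPONENT_PAIRS = (
    ("Ex_x", "Eu_x"),
    ("Ex_x", "Ev_x"),
    ("Ey_x", "Eu_x"),
    ("Ey_x", "Ev_x"),
    ("Eu_x", "Ev_x"),
    ("Ex_y", "Eu_y"),
    ("Ex_y", "Ev_y"),
    ("Eu_y", "Ev_y"),
)


def pair_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}-{pair[1]}"


@dataclass(frozen=True)
class CorrelationSet:
    """The 8 component correlations r_C of one run and the window used.

    ``rC`` maps pair names (e.g. ``"Ex_y-Eu_y"``) to Spearman coefficients
    in [-1, 1]; a pair involving a constant (zero-variance) component maps
    to NaN — undefined, never coerced to zero.
    """

    rC: dict[str, float]
    window: tuple[float, float]


def component_correlations(
    cs: ComponentSeries, window: float = CORRELATION_WINDOW
) -> CorrelationSet:
    """Spearman r_C for the 8 admissible pairs over the trailing window.

    Ties receive average ranks.  The window is the last ``window`` model
    time units of the series.
    """
    t_start = cs.times[-1] - window
    tail = cs.window(t_start)
    values: dict[str, float] = {}
    for pair in COMPONENT_PAIRS:
        a = tail.component(pair[0])
        b = tail.component(pair[1])
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            values[pair_name(pair)] = float("nan")
            continue
        rho = spearmanr(a, b).statistic
        values[pair_name(pair)] = float(rho)
    return CorrelationSet(rC=values, window=(float(tail.times[0]), float(tail.times[-1])))
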