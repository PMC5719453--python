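"""Shared fixtures: the three reference parameter regimes.

The three regimes span the phenomenology the analysis is built around:
slow predator adaptation (antiphase cycles), fast predator adaptation
(quarter-lag cycles), and costly defense with long handling time
(quarter-lag cycles of a different origin).  Their 50,000-unit
trajectories are expensive, so they are integrated once per session.
"""

import numpy as np
import pytest
from hypothesis import settings

from coevodyn import AdaptationParams, ModelParams, SimConfig, integrate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

REGIMES = {
    # slow symmetric adaptation -> antiphase cycles
    "antiphase_slow": (ModelParams(), AdaptationParams(Gx=1e-2, Gy=1e-2)),
    # rapid predator adaptation -> quarter-lag cycles
    "quarter_fast_predator": (ModelParams(), AdaptationParams(Gx=1e-1, Gy=10**-0.9)),
    # costly defense, long handling time -> quarter-lag cycles
    "quarter_costly_defense": (
        ModelParams(cx=5.0, cy=2.0, h=2.0),
        AdaptationParams(Gx=1e-2, Gy=1e-2),
    ),
}


@pytest.fixture(scope="session")
def regime_trajectories():
    """Full-horizon trajectories of the three reference regimes."""
    return {
        name: integrate(p, a, SimConfig())
        for name, (p, a) in REGIMES.items()
    }


@pytest.fixture(scope="session")
def antiphase_traj(regime_trajectories):
    return regime_trajectories["antiphase_slow"]


@pytest.fixture(scope="session")
def quarter_lag_traj(regime_trajectories):
    return regime_trajectories["quarter_fast_predator"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
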