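"""Fourier phase-lag estimation between oscillatory series.

The phase lag of a follower series behind a reference series is read off
the cross-spectrum at the reference's dominant (highest-power, nonzero)
Fourier frequency.  It is expressed as a fraction of the dominant period
in [-1, 0]: 0 (or -1) means in phase, -0.25 the classic quarter-period
predator lag, -0.5 antiphase.  Both series are mean-removed; no taper is
applied (the analyzed series are long and near-periodic, so leakage at the
shared peak bin affects both spectra alike and largely cancels in the
phase difference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observables import EffectiveBiomassSeries, effective_biomass_series
from .simulation import Trajectory

__all__ = [
    "PhaseResult",
    "PhaseUndefinedError",
    "PHASE_WINDOW",
    "phase_lag",
    "classify_phase",
    "all_phase_relationships",
]

#: Span (model time units) at the end of the horizon used for spectra.
PHASE_WINDOW = 20_000.0

#: Relative-variation floor below which a series counts as flat.
_FLAT_RTOL = 1e-9

#: The dominant peak must carry at least this multiple of the mean
#: nonzero-frequency power, otherwise no cycle is present.
_PEAK_TO_MEAN_MIN = 10.0


class PhaseUndefinedError(ValueError):
    """No dominant spectral peak: the series is flat or non-cyclic."""


@dataclass(frozen=True)
class PhaseResult:
    """Phase lag ``phi`` in [-1, 0], dominant period, and cycle label."""

    phi: float
    period: float
    label: str


def phase_lag(reference, follower, dt_sample: float = 1.0) -> PhaseResult:
    """Phase lag of ``follower`` behind ``reference`` in cycle fractions.

    The dominant frequency is the nonzero bin maximizing the reference's
    power spectrum; phi is the cross-spectrum phase there, mapped into
    [-1, 0] so that a follower peaking a quarter period late gives -0.25
    and an antiphase follower gives -0.5.  Raises
    :class:`PhaseUndefinedError` for flat or peak-less series.
    """
    reference = np.asarray(reference, dtype=float)
    follower = np.asarray(follower, dtype=float)
    if reference.shape != follower.shape or reference.ndim != 1:
        raise ValueError("series must be 1-d and of equal length")
    scale = 1.0 + np.abs(reference).max()
    if reference.std() < _FLAT_RTOL * scale:
        raise PhaseUndefinedError("reference series is flat")
    ref = reference - reference.mean()
    fol = follower - follower.mean()
    ref_fft = np.fft.rfft(ref)
    fol_fft = np.fft.rfft(fol)
    power = np.abs(ref_fft[1:]) ** 2
    k = 1 + int(np.argmax(power))
    if power[k - 1] < _PEAK_TO_MEAN_MIN * power.mean():
        raise PhaseUndefinedError("no dominant spectral peak above noise floor")
    period = len(ref) * dt_sample / k
    # cross-spectrum phase: arg F_fol - arg F_ref; a pure delay tau gives
    # -tau/period, already negative for a lagging follower
    phi = float(np.angle(fol_fft[k] * np.conj(ref_fft[k])) / (2.0 * np.pi))
    if phi > 0.0:
        phi -= 1.0
    return PhaseResult(phi=phi, period=period, label=classify_phase(phi))


def classify_phase(phi: float, band_halfwidth: float = 0.1) -> str:
    """Label a phase lag: in_phase, quarter_lag, antiphase or intermediate.

    Bands of half-width ``band_halfwidth`` are centered on -0.25
    (quarter_lag) and -0.5 (antiphase); lags within the half-width of 0 or
    -1 are in_phase; everything else is intermediate.
    """
    if not -1.0 <= phi <= 0.0:
        raise ValueError("phi must lie in [-1, 0]")
    w = band_halfwidth
    if phi > -w or phi < -1.0 + w:
        return "in_phase"
    if -0.25 - w <= phi <= -0.25 + w:
        return "quarter_lag"
    if -0.5 - w <= phi <= -0.5 + w:
        return "antiphase"
    return "intermediate"


def all_phase_relationships(
    traj: Trajectory, xeff: EffectiveBiomassSeries | None = None
) -> dict[str, PhaseResult]:
    """The three phase relationships of a cycling run.

    Returns ``phi_xy`` (predator behind prey), ``phi_xeffy`` (predator
    behind effective prey biomass) and ``phi_xxeff`` (effective behind
    actual prey biomass), each computed over the last ``PHASE_WINDOW``
    time units of the trajectory.
    """
    if xeff is None:
        xeff = effective_biomass_series(traj)
    t_start = traj.times[-1] - PHASE_WINDOW
    win = traj.window(t_start)
    mask = xeff.times >= t_start - 1e-9
    xeff_win = xeff.x_eff[mask]
    dt = traj.config.dt_sample
    return {
        "phi_xy": phase_lag(win.x, win.y, dt),
        "phi_xeffy": phase_lag(xeff_win, win.y, dt),
        "phi_xxeff": phase_lag(win.x, xeff_win, dt),
    }
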