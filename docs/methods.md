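# Methods

## Model and assumptions

The simulator couples Rosenzweig–MacArthur-type ecology (logistic prey,
Holling type II predation, constant predator mortality) to quantitative-
genetics trait dynamics. Both traits are scalar and unidirectional: the
attack rate depends only on the difference `u - v` through a logistic
function with steepness `theta`, so defense and offense are an arms race
along one axis. Trade-offs are Gaussian in the trait (`r(u) = r0·exp(-cx
u²)`, `g(v) = g0·exp(-cy v²)`): cost-free at zero investment, with
curvature set by the costliness parameters. Trait velocities are
proportional to the analytic fitness gradients times the additive genetic
variances `Gx`, `Gy`; a smooth boundary factor `exp(-eps/trait)` (with
`eps = 1e-3`) stalls evolution near zero so traits cannot become negative.
Populations are unstructured and deterministic; there is no mutation
limitation, no demographic stochasticity, and genetic variances are
constant within a run.

The model admits a purely ecological reduction: with `Gx = Gy = 0` and
both traits held at zero the system is the classical Holling type II
predator–prey model, whose interior equilibrium
`x* = d/(a(g0 − d·h))`, `y* = r0(1 − x*/K)(1 + a·h·x*)/a` (with
`a = a0/2` at equal traits) is used as an independent correctness check.
To make this limit expressible, trait states are allowed to *be* zero
(they are then frozen, since the boundary factor vanishes); an evolving
run never reaches zero from a positive start.

## Parameters

Defaults are the standard values of the adaptation-speed analysis:
`r0 = K = a0 = g0 = 1`, `theta = 10`, `d = 0.1`, `h = 0.1`, `cx = 3`,
`cy = 2`, `Gx = Gy = 1e-2`. The cost analysis uses `h = 1` and scans
`cx, cy ∈ [0, 10]` linearly; speed grids scan `Gx, Gy ∈ [10^-2.5, 1]`
log-spaced (the exponents, not the values, are the natural axis). Units:
time is set by `1/r0`, biomass by `K`; `Gx, Gy = 1` would make evolution
as fast as ecology.

Trade-off shapes are pluggable behind a two-method interface (`value`,
`derivative`) so alternative cost structures can be studied without
touching the solver; the Gaussian forms are the default and the only
shapes exercised by the test suite.

## Numerics

Integration uses LSODA (stiff-capable, adaptive) with `rtol = 1e-8`,
`atol = 1e-10`, over a 50,000 time-unit horizon sampled every 1 time unit.
The first 30,000 units are discarded as transient, phase spectra use the
last 20,000, and component correlations plus the equilibrium test use the
last 5,000. Initial condition `x = 0.5, y = 0.3, u = v = 0.1` is
arbitrary; the long transient discard makes the attractor determine every
reported quantity, which a sensitivity test (different initial state, same
phase lag to < 0.01) confirms. Halving the solver tolerances moves the
estimated phase lag by < 1e-3.

The logistic attack-rate exponent is clamped at ±700 before
exponentiation, so extreme trait gaps saturate the rate at `a0` or ~0
instead of overflowing. Biomass undershoots below zero are accepted only
within 10·`atol` and clipped; anything larger aborts the run. Outcome
classification: predator extinct if its biomass ever falls below 1e-9
after the transient; stable equilibrium if the coefficients of variation
of both biomasses over the last 5,000 units are below 1e-4; cycles
otherwise. Both thresholds sit many orders of magnitude away from the
amplitudes of observed cycles.

## Geber decomposition

Each component is the analytic partial derivative of `W_x` or `W_y` times
the analytic time-derivative of the corresponding variable — the
decomposition is exactly the multivariate chain rule and involves no
numerical differentiation, so the components sum to `dW/dt` identically up
to solver error. The test oracle for this identity is a centered
finite difference of the sampled fitness series. At unit sampling the
truncation error of a 2nd-order stencil ((ω·dt)²/6 ≈ 2e-3 for the
shortest observed periods, ~60 time units) exceeds the 1e-3 band the
identity is certified to, so the certifying oracle is an 8th-order
centered stencil, whose truncation error is 1–2 orders below the band;
a separate test confirms the 2nd-order discrepancy is pure truncation by
checking it shrinks ∝ dt². Relative error is measured against the maximum
magnitude of the derivative series over the window, since pointwise
relative error is undefined at the derivative's zero crossings.

## Phase estimation

The phase lag φ of a follower behind a reference series is the
cross-spectrum phase at the reference's dominant nonzero FFT frequency,
both series mean-removed, mapped into [−1, 0] (0 in phase, −0.25 quarter
lag, −0.5 antiphase). No taper is applied: the analyzed windows hold ≥ 30
cycle periods and leakage at the shared peak bin largely cancels in the
phase difference. The estimator is exact to float precision on bin-centered
sinusoids, within 0.01 at SNR ≈ 10, and invariant to affine rescaling and
common window shifts. A series whose peak spectral power is less than 10×
the mean nonzero-frequency power (or whose variance is negligible) has no
defined phase; in the pipeline this path is only reached by non-cycling
runs, which are filtered out by outcome classification first.

Phase classification uses bands of half-width 0.1 around −0.25
(quarter-lag) and −0.5 (antiphase), with in-phase within 0.1 of 0 or −1
and an explicit intermediate class between bands; the width is
configurable, and intermediate lags do occur in narrow transition regions
of the parameter space.

## Correlations and associations

Component correlations `r_C` are Spearman coefficients (average ranks on
ties) over the last 5,000 time units. Of the 12 possible pairs, 8 are
admissible: the two prey-vs-predator-biomass pairs restate the phase
relationship itself and every pair with the identically-zero `Ey_y` is
degenerate. Constant components yield an undefined (NaN) correlation,
never a zero. Raw components are used — rank correlation is invariant to
the positive per-series rescaling that plotting standardization applies.

Per set (one grid over two focal parameters), the association `r_A` of a
pair is the Spearman correlation between `phi_xy` and that pair's `r_C`
across the cycling cells where both are defined; cells classified as
equilibrium or extinct carry no phase and are excluded. All cycling cells
enter, including intermediate-phase ones. A set is included in the family
aggregate only if its cells contain both an antiphase and a quarter-lag
cycle and at least 3 cells are usable; the aggregate is the mean and
(population) standard deviation across included sets.

## Problem sizes

The full published-scale families (96 speed + 126 cost sets of 25 × 25
cells) are available through the sweep API and CLI but amount to ~10⁵
long integrations. The replication surface used by the tests and the
acceptance script is a reduced speed-analysis family — four sets
(`K ∈ {1, 2} × cx ∈ {2, 3}`, all else standard) on 9 × 9 log-spaced
`Gx × Gy` grids — which reproduces the strong positive association of the
`Ex_y-Eu_y` pair (mean `r_A` ≈ 0.93 over the included sets, against the
full-scale value 0.91) in a few minutes on one CPU. In this reduced
family the `cx = 2` sets are excluded by the inclusion rule: with cheap
defense the prey escapes predation over most of the grid and the predator
collapses, so no quarter-lag cells exist there.

## Known limitations

* One prey, one predator, one scalar trait each; no bidirectional trait
  axes, multi-clone polymorphism, plasticity or stochasticity.
* The sign of the association for the `Ex_x-Ev_x` pair on the reduced
  family is strongly negative (≈ −0.77) while its magnitude matches the
  full-scale analysis; only the `Ex_y-Eu_y` pair's association is used as
  a replication target, and the qualitative sign dictionary of the
  per-regime correlations is verified directly on single runs.
* Phase estimation assumes a single dominant frequency; quasi-periodic or
  chaotic dynamics (not observed in the studied ranges) would need
  time-resolved methods.
* Outcome classification is threshold-based; trajectories that pass
  arbitrarily close to extinction while still cycling deterministically
  are classified as extinctions by design (a biologically reasonable
  reading of predator densities below 1e-9).
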