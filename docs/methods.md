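# Methods

## Model and assumptions

`extruflow` models pneumatic extrusion of a power-law fluid,
τ = K·γ̇ⁿ, through an axisymmetric nozzle. The assumptions are those of
lubrication-style pipe flow: steady, axisymmetric flow; no slip at the
nozzle wall; a force balance on each thin cross-section between the
pressure difference and the wall shear stress; and the tube-flow wall shear
rate γ̇ = ((3n+1)/(4n))·4Q/(πr³) — the Newtonian value times the
Rabinowitsch factor — applied locally at each axial station. Integrating
the resulting local pressure gradient from the inlet (z = 0, at the top) to
the tip (z = L) gives

    ΔP = 2K · ((3n+1)/(4n) · 4Q/π)ⁿ · I(n),   I(n) = ∫₀ᴸ r(z)^−(3n+1) dz.

Everything geometric enters through I(n). Conical nozzles (linear taper
Di → Do over Lc) and straight bores (DN, LN) have closed forms

    I_cone = (r_iᵖ − r_oᵖ) / (p·tanθ·(r_i r_o)ᵖ),  p = 3n,
    I_straight = L_N / R_N^(3n+1),

with tanθ = (r_i − r_o)/Lc; arbitrary profiles are integrated by adaptive
quadrature (`scipy.integrate.quad`, relative tolerance 1e−10), with
tabulated profiles linearly interpolated between samples. A cone whose
taper is below 1e−12 relative dispatches to the cylindrical form, which is
its analytic limit (the conical expression is 0/0 there).

Downstream, the extruded thread is assumed to keep a circular cross-section
until it is dragged onto the platform at travel speed U, so flux balance
Q = π d² U / 4 yields the printed width d = √(4Q/(πU)). Die swell, yield
stress (viscoplasticity), wall slip and temperature dependence of (n, K)
are outside the model. The set air pressure on a pneumatic printer is
treated directly as the gauge pressure drop ΔP across the nozzle: the
syringe barrel is much wider than the tip, so its pressure drop is
neglected, and the tip discharges at atmospheric pressure (101 325 Pa).
Build-platform and nozzle travel speed are interchangeable in the flux
balance.

## Parameters and units

Everything internal is SI (m, Pa, m/s); unit handling (kPa, mm, mm/s)
lives only in the I/O layer and CLI. Key parameters:

- **n** (dimensionless): flow behaviour index, working range [0.01, 2].
  The lower bound keeps the 1/n exponents numerically safe (1/n = 100 at
  the bound); fitted indices for printable inks sit well inside it.
  Terms of the form x^(1/n) and x^n are evaluated in log space so small n
  cannot overflow Pa-scale bases.
- **K** (Pa·sⁿ): consistency index, > 0. Equals the dynamic viscosity μ at
  n = 1.
- **ΔP** (Pa, gauge): pressure drop, ≥ 0. **U** (m/s): travel speed, > 0.
- **a** (m·Pa^−(1/2n)): width-law coefficient, d = a·ΔP^(1/2n), for widths
  in metres and pressures in Pa. Its published counterparts carry no stated
  units; SI is the convention consistent with their magnitudes
  (a ≈ 8.93e−9, ΔP = 3e4 Pa ⇒ d ≈ 0.7 mm).
- **ε** (dimensionless): two-sided relative width tolerance of the
  printability window, default 0.05. The source treatment says only "to
  some small tolerance"; 5 % is this package's choice, and two-sided
  because under- and over-extrusion are both misprints.
- **α**: significance level for FDR-adjusted residual flags, default 0.05.

The built-in conical tip catalogue (25G/22G/20G: outlet diameters 0.25,
0.41, 0.58 mm; shared 4.02 mm inlet) deliberately omits the tapered length
Lc, which varies by manufacturer and was not published for the validation
experiments; it must be supplied by the caller. Converting between a and K
requires Lc, so fits report K only when the full geometry and travel speed
are given.

## Inverse fitting

The free fit minimises Σᵢ (d̄ᵢ − a·ΔPᵢ^(1/2n))² over (a, n), where d̄ᵢ are
per-pressure mean widths. At fixed n the optimal a is linear least squares
with closed form a = Σxᵢd̄ᵢ/Σxᵢ², xᵢ = ΔPᵢ^(1/2n); profiling a out reduces
the problem to one dimension in n. A deterministic seed grid
(n = 0.05…1.5, step 0.05) followed by bounded scalar minimisation
(parameter tolerance 1e−12), plus one full-range refinement pass, makes the
optimiser seed-free and immune to local minima on this smooth profile; ties
break toward smaller n. The regressor is computed in the scaled basis
(ΔP/ΔP_max)^(1/2n) so extreme exponents cannot overflow. Newtonian
(n = 1) and fixed-n fits use the same closed form directly. The free fit
demands ≥ 3 distinct pressures (two points determine (a, n) exactly and
leave nothing to validate); fixed-n fits demand ≥ 2. R² is computed about
the mean of the per-pressure means.

Aggregation convention: width measurements arrive as
pressure → repeat → line → position records. Positions are averaged into
line means; line means, pooled across repeats, average into the
per-pressure mean that the fit sees. This matches how such experiments
summarise their prints. Whether the original study fitted per-pressure
means or raw measurements is not documented, so a `raw` convention is also
provided on both the fitter and the residual tests.

The rheometer route fits ln μ = ln K + (n−1)·ln γ̇ by ordinary least
squares on log-transformed viscosity/shear-rate pairs; it is provided for
cross-checking fitted indices against rotational-rheometry data.

## Residual validation

For each pressure, residuals are line-mean widths minus the fitted curve;
a two-sided one-sample Student t-test (df = m − 1 over the m line means)
tests zero mean, and an uncorrected 95 % CI half-width is reported. The
per-pressure p-values are adjusted jointly by the Benjamini–Hochberg
step-up procedure (via `statsmodels`); a pressure is flagged when its
q-value falls below α. Degenerate residual sets — one residual, or zero
variance — carry no evidence of misfit and are assigned p = 1 rather than
an error; this arises for noiseless synthetic data. The "FDR correction"
of the original analysis names no specific procedure; Benjamini–Hochberg
is the standard step-up choice.

## Synthetic experiments

The generator reproduces the validation protocol's structure: a list of
gauge pressures (default 60–75, 77, 80 kPa — quantised to the 1 kPa gauge
display before the forward model is evaluated), 3 repeated prints per
pressure, 9 lines per print, 3 width measurements per line, at 5 mm/s.
Each measurement is the forward-model width times (1 + ε) with
ε ~ N(0, 0.05) i.i.d. — multiplicative noise, because measured spread
grows with width; an additive mode (sd scaled off the tip diameter) is
available. Widths are floored at 1 µm so invariants survive extreme draws.
The true measurement-noise magnitude of the original experiments is
unreported; 5 % is a placeholder calibrated only by plausibility.

Ground truth defaults are n = 0.165, K = 560 Pa·sⁿ, with a 22G conical tip
and an assumed Lc = 30 mm. The index matches the soft-colloid fits; the
consistency index is chosen so that, with this tip length, the forward
model reproduces the observed behaviour — widths of ≈ 0.37–0.89 mm across
60–80 kPa, a width-matching optimum at 62 kPa, and an implied width-law
coefficient a ≈ 1.23e−18, essentially the published 1.220e−18 for this
tip. (The published K ≈ 10 Pa·sⁿ cannot reproduce these widths under any
plausible tip length, because the a↔K conversion depends on the
unpublished Lc; a and n, not K, are the reproducible quantities.) Note
what passing synthetic tests do *not* show: the generator has no die
swell, no start-of-line transients, no drift or clogging, no within-line
correlation, and noise that is exactly Gaussian — recovery performance on
real prints will be worse than on these idealised datasets.

## Numerical choices and degenerate inputs

- Quadrature: adaptive, relative tolerance 1e−10, limit 200 subintervals;
  non-convergence raises rather than returning a degraded value.
- Closed forms and the quadrature path agree to better than 1e−8 relative
  across n ∈ [0.05, 1.5] and the catalogue geometries (tested).
- ΔP = 0 or Q = 0 return zero flux/width exactly rather than erroring.
- Cones with Di = Do, profile tables, and negative or non-positive
  geometry all fail loudly at construction, not at evaluation.
- CSV output uses shortest-round-trip decimal formatting and the reader
  parses with correctly-rounded conversion, so an SI write/read cycle is
  bit-identical.

## Problem sizes

The test suite and the reproduction script run synthetic experiments at
the protocol's own scale (18–20 pressures × 81 measurements), 50 seeded
replicates for recovery statistics, and 400 replicates for the
false-flag-rate check; the whole suite completes in a few seconds on one
core. These sizes give stable medians and rates without pretending to more
precision than 50 replicates can support.

## Known limitations

- Power-law only: no yield stress (Herschel–Bulkley), so the model
  predicts flow at arbitrarily small stresses and can mislead for strongly
  viscoplastic inks.
- No die swell or free-surface mechanics at the tip; the circular
  cross-section assumption ignores spreading on the platform.
- (n, K) are treated as constants; temperature and concentration
  dependence must be handled by refitting.
- The a↔K conversion is exactly as good as the supplied Lc.
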