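# Methods

This note documents the models, the numerical choices, and the synthetic
data design — what is computed, under which assumptions, and where the
design was genuinely open.

## Respirometry rates

Each replicate is one sealed 0.8 mL chamber holding two polyps, recorded
for one hour in darkness and one hour in light at 1 Hz. The oxygen slope
β (mg O₂ L⁻¹ s⁻¹) is estimated by ordinary least squares over the trace
after discarding an initial settling window (default 300 s, configurable);
gentle-agitation events during incubation are not modelled as
discontinuities — a single slope is fit over the whole retained window.
Rates are standardized as

- RR = |(β_dark − β_control)| · 3600 · Vol / DW,
- NPP = (β_light − β_control) · 3600 · Vol / DW (sign preserved; negative
  NPP means net oxygen consumption under light),
- GPP = NPP + |RR|, assuming holobiont respiration is constant over the
  daily cycle.

RR is stored as a magnitude; the consumption sign convention lives only in
the slope. Control subtraction is always applied when a control chamber is
present (a flat control is an exact no-op); if the control slope exceeds
the experimental one in magnitude the event is logged, not raised. The
per-temperature summary reports mean ± standard error (ddof = 1); the SE is
reported missing for a single replicate rather than zero.

Out of scope by design: optode drift and temperature compensation,
oxygen-solubility corrections, and any mortality scoring beyond the
synthetic design below.

## TPC model family and fitting

Seven unimodal rate-versus-temperature forms are fit to replicate-level
points (not temperature means): the enzyme-kinetics form with explicit
optimum ("Pawar"; 4 parameters r_tref, E, E_h, T_opt with T_ref fixed at
15 °C and k = 8.62·10⁻⁵ eV K⁻¹), the full Sharpe–Schoolfield model with
both low- and high-temperature inactivation (6 parameters), Gaussian,
quadratic, Brière-II, Ratkowsky and a re-parameterized Weibull whose
maximum a occurs at t_opt. Kelvin conversion is fixed at T(K) = T(°C) +
273.15.

Two notes on the family's composition:

- The Pawar parameterization satisfies an analytic identity — the curve's
  maximizer equals the T_opt parameter — which the tests assert over random
  parameter draws.
- The *high-deactivation-only* Sharpe–Schoolfield variant is exactly the
  same curve family as the Pawar form (T_h and T_opt are two
  parameterizations of one shape). Including both would make AIC selection
  between them a coin flip on any data, so the family carries the full
  6-parameter Sharpe–Schoolfield instead: it nests the Pawar shape, fits at
  least as well, and pays the parsimony penalty — selection then measures a
  real trade-off.

Each model is fit by bounded nonlinear least squares (`scipy`'s
trust-region reflective) from 20 Latin-hypercube start points drawn inside
a data-derived parameter box (seed 1234 by default); the lowest-RSS
converged start wins. Data are canonically sorted before fitting, so the
result is invariant to input order, and everything downstream of a seed is
bit-reproducible. Model choice uses the Gaussian-likelihood AIC,
n·ln(RSS/n) + 2(p + 1), counting the error variance as a parameter; only
AIC differences matter for ranking. Ties break to fewer parameters, then
lexicographic model id. A perfect fit (RSS = 0) is ranked best via a −∞
sentinel. Weighted NLS, AICc/BIC and Bayesian fitting are deliberate
non-goals.

## Bootstrap bands

95 % bands are case-resampling (pairs) bootstrap: resample replicates with
replacement, refit the selected model (warm-started at the original
estimate plus fresh multi-starts), evaluate on a temperature grid, and take
per-grid-point 2.5/97.5 percentiles over replicates (999 by default for
reporting; the pipeline default is 199, which changes band edges by less
than the plotted linewidth at this noise level). The band is widened where
necessary to contain the point prediction, so "curve inside band" holds by
construction at every grid temperature. Refit failures above 50 % abort
with advice to increase starts. These are percentile bands of the fitted
curve — sampling uncertainty of the fit, not prediction intervals for new
replicate observations — and are labelled as such.

## Critical thermal limits

The published limits for this system were stated as extrapolations without
a printed operational definition. Here CTmin/CTmax are *defined* as the
temperatures where the fitted curve falls to a threshold fraction θ of its
peak rate, found by bisection on each limb of the curve over [−20, 60] °C
(the peak itself by 0.01 °C grid argmax refined to ~10⁻⁸ °C). The default
θ = 0.098 is calibrated once so that the published, rounded respiration
parameters reproduce both published limits (6.4 and 39.0 °C) to one
decimal; θ is a config knob and reports include a sensitivity table over
θ ∈ {0.05, 0.098, 0.15}. With the independently printed (rounded) GPP
coefficients the same θ lands within 0.15 °C of the published CTmax but
0.37 °C below the published CTmin — the curves were printed with identical
limits, which rounded parameters cannot exactly reproduce; the discrepancy
is reported, not forced away.

## Thermal habitat suitability

THS(T) = rate(T)/rate(T_opt), clipped to [0, 1]; it is scale-free in the
rate units (r_tref cancels), equals 1 exactly at the optimum, and is left
as the small positive ratio below CTmin rather than clamped to zero (winter
maps legitimately show low-but-nonzero classes). Projection onto a monthly
SST raster masks land (NaN) and cells deeper than the bathymetry cutoff
(50 m default — the benthic polyp's habitat); a single mask convention
propagates through classification with no interpolation. Classes use edges
{0, 0.2, 0.4, 0.6, 0.8, 1.0}, half-open [a, b) with the top bin closed so a
score of 1 counts in 0.8–1.0. Percentages are unweighted cell counts over
unmasked cells; latitude-area weighting was considered and rejected as the
default because the published class tables are plain percentages of
coastal area. Scenario deltas are per-class percentage-point differences
(future − current) at matching months and edges; they sum to zero by
construction. Real-raster regridding, dispersal and medusa-stage phenology
are out of scope.

## Synthetic data

The generator emulates the laboratory design: 15 target temperatures
(12–40 °C step 2), 7 replicate chambers + 1 polyp-free control per
temperature, two polyps per chamber with pair dry weight ~N(1.210,
0.007²) mg, 0.8 mL chambers, 1 h dark + 1 h light at 1 s sampling, traces
starting near air saturation (8 mg O₂ L⁻¹). True dark-phase rates follow a
Pawar curve; the light phase uses NPP_true = c·GPP_true − RR_true, with
GPP_true a second Pawar curve (height tracking the respiration curve) and
c calibrated once so the NPP/RR crossover sits at 32 °C, the observed
crossover point. Two stochastic layers:

- a per-chamber lognormal "condition" factor (CV 0.115, applied to both
  phases) emulating inter-individual metabolic variability, anchored to
  the observed replicate dispersion (s.d. ≈ 0.07 around the 0.61 peak
  rate) — without it, synthetic rates are orders of magnitude more precise
  than any real experiment and AIC begins resolving curve differences that
  real data cannot;
- Gaussian noise on each oxygen reading (0.01 mg L⁻¹ default, optode
  precision), applied at measurement level so slope-estimation variance
  propagates realistically.

Mortality is emulated (flag default on) as seeded replicate dropout: each
chamber dies with probability 0.2 at 16, 18 and 38 °C (at least one
survivor kept) and all chambers at 40 °C, so fitting faces the same
unbalanced design the experiment produced. Setting noise_sd = 0 and
biological_cv = 0 makes the pipeline invert the generator exactly — the
self-consistency oracle used throughout the tests.

The climatology generator produces a Mediterranean-like basin on a regular
lat-lon grid (default 40 × 60 over 30–46° N): SST(month, cell) =
latitudinal base (20 °C at mid-basin, −0.3 °C per degree north) + 7 °C
seasonal sinusoid peaking in August + spatial noise (s.d. 0.5 °C) +
scenario offset, giving basin means near 27 °C in August and 13 °C in
February. Scenario offsets are purely additive after the noise draw
(current 0, RCP 4.5 +0.8 °C, RCP 8.5 +1.5 °C by 2050 — typical mid-century
Mediterranean surface-warming magnitudes), so same-seed rasters differ
between scenarios by an exact constant. Bathymetry is a shelf deepening
with distance from a jittered synthetic coastline; the first offshore ring
sits at 2 m and depth crosses the 50 m cutoff `shelf_width` cells out, so
land, shallow and deep cells always coexist. What this does *not* emulate:
real coastline geometry, CMIP-forced spatial warming patterns,
heat-budget dynamics — so passing map tests demonstrates the projection
and accounting machinery, not a validated Mediterranean forecast.

## Problem sizes and determinism

Tests run the full 15-temperature design with 30 s sampling (the slope
algebra is sampling-rate-exact; only noise propagation changes) and the
parameter-recovery study uses 50 experiments at 1 s sampling. One
top-level seed fixes every artifact bit-exactly: generators, multi-start
draws, bootstrap resampling and mortality all derive from explicit seeds,
and pipeline reruns with the same config reproduce CSV and report bytes.

## Known limitations

- The CT-limit definition (fraction-of-peak threshold) is one defensible
  operationalization of "critical temperature"; others (inflection points,
  absolute-rate floors) would give different values, which is why θ is
  exposed and a sensitivity table is always emitted.
- The bootstrap quantifies fit uncertainty conditional on the selected
  model; model-selection uncertainty is visible in the AIC table but not
  propagated into the bands.
- GPP inherits dark-phase RR measured separately; any light-enhanced
  respiration violates the GPP = NPP + |RR| bookkeeping identically in the
  laboratory formula and here.
- Suitability is temperature-only: salinity, food, light and dispersal are
  outside the trait model.
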