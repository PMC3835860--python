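# Methods

This note records the statistical models behind `driftgrid`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Concentration conventions

A manta net (0.86 × 0.2 m mouth) samples the air–sea interface, so the
natural unit is particles per m² of sea surface. The area swept is the
filtered volume divided by the 0.2 m vertical mouth dimension; hence
`conc_m2 = count / (volume_m3 / 0.2)` and, identically,
`conc_m2 = 0.2 · conc_m3`. Zooplankton dry masses are corrected for
preservation loss by multiplying the measured mass by 1.20. The
alternative reading — dividing by 0.8, i.e. +25% — is defensible, but the
package takes "a 20% correction factor was applied" literally as adding
20% of the measured value. Removal equivalents invert the
plastic-to-plankton mass ratio r: 1000/r mg of zooplankton dry biomass per
gram of plastic, times a carbon fraction (default 0.40) for the carbon
equivalent. At r = 1.368 this gives 731 mg zooplankton and 292.4 mg
carbon; note 731 × 0.40 is 292.4, not the ≈330 sometimes quoted alongside
these inputs — the package reports the arithmetic.

Summary statistics use linear-interpolation (type 7) percentiles, CV =
100·SD/mean, and a percentile bootstrap (B = 1000, seeded) of the median,
resampling tows. Group comparisons are nonparametric throughout: two-sided
Mann–Whitney U with tie correction, Kruskal–Wallis for k groups, and
pairwise rank-sum comparisons with Holm family-wise adjustment as the
post-hoc — the same decision structure as a Nemenyi-type procedure, chosen
for its simpler exact definition. Trend lines on skewed scatter use the
Theil–Sen single-median method (median pairwise slope; intercept =
median(y − slope·x)).

## Semivariography

Both the classical moment estimator and the Cressie–Hawkins robust
estimator are implemented; the robust form is the default because
concentration data are strongly right-skewed and the classical estimator
is dominated by the largest pairwise differences. The Cressie–Hawkins
denominator is 2(0.457 + 0.494/|N(h)|).

Distances are great-circle (haversine, R = 6371 km). Coordinates in a
basin-scale survey are geographic, and treating degrees as planar
coordinates distorts east–west distances by cos(latitude) — material at
20–40°N — so the spherical distance is used even where a plane would be
conventional. Default binning is 15 equal-width bins to half the maximum
pairwise distance; bins with no pairs are dropped.

Model fitting is weighted least squares with weights equal to pair counts.
The Gaussian model is γ(h) = τ² + σ²(1 − exp(−(h/φ)²)); the *practical*
range (95% of the sill) is φ√3, and both are reported to avoid the
parameterization ambiguity between software traditions. The fit
multi-starts φ over a log-spaced grid (8 starts, 0.05–2 × max lag) with
bounds τ², σ² ≥ 0, φ > 0 and tolerances 1e-8, because the Gaussian model's
likelihood surface in φ is multimodal on noisy empirical variograms. The
linear family γ(h) = a + bh permits b < 0: a negative empirical slope is
an artifact signature (close pairs more different than distant ones),
worth fitting precisely so it can be reported.

## Distance sampling

Sightings arrive pre-binned (0–10, 10–50, 50–100, 100–200, 200–300,
300–600, >600 m; one-sided transect), so detection functions are fitted by
maximizing the multinomial log-likelihood with cell probabilities
p_j ∝ ∫_bin g(x) dx / ∫_0^W g(x) dx. The candidate set is uniform,
half-normal and hazard-rate without adjustment terms: six closed bins
cannot identify key-plus-adjustment expansions, and these three cover the
flat, shoulder and spiked shapes. Selection is by AIC = 2k − 2ℓ.

Truncation is at W = 600 m, the last closed bin edge. The open ">600 m"
bin is excluded from fitting because an unbounded cell has no finite
integral under uniform detection; the synthetic generator still produces
such sightings, flagged, so the bookkeeping round-trips. Groups (3 size ×
3 colour classes) with fewer than 10 sightings are pooled into their size
class before fitting.

ESW = ∫₀ᵂ g dx by adaptive quadrature (relative tolerance 1e-8); for the
half-normal there is the closed form σ√(π/2)·erf(W/(σ√2)) used as a
cross-check. Densities standardize each group to the widest-ESW group:
CF_g = ESW_max/ESW_g, density_g = n_g·CF_g/(L·ESW_max) = n_g/(L·ESW_g).
Confidence intervals bootstrap transect segments (the independent sampling
unit) with replacement, refitting the detection function per replicate;
percentile 95% intervals. Half-normal fits use bounded scalar minimization
over log σ; hazard-rate uses L-BFGS-B in log-parameters with 5 seeded
random restarts. No sea-state covariate enters the detection model.

## Monte Carlo power and sampling adequacy

Power for detecting a multiplicative increase is estimated by resampling:
both groups are drawn with replacement from the empirical base sample
(size n each), the treatment group multiplied by the factor, and a
two-sided Mann–Whitney U at α = 0.05 applied; power is the rejection
fraction over 1000 replicates per cell (MC SE = √(p(1−p)/reps)). The test
inside the loop is a vectorized normal approximation with tie correction
and continuity correction — resampled data always contain ties, and the
per-cell test must be cheap; it is verified against an independent
reference implementation in the tests. Two-sided testing is the
conservative choice where the direction of change is not pre-specified.
Group sizes are per group, not total. A master seed spawns per-cell
substreams, so any cell is reproducible in isolation.

The sample-size search smooths the power-versus-n curve by isotonic
regression before reading off the threshold crossing: raw MC jitter of one
standard error otherwise makes the crossing seed-sensitive. An unattained
target is reported as such, never extrapolated.

The adequacy simulation draws exponential(rate) datasets — rate defaults
to 1.44 m² per particle, the ML fit of the combined survey data — for
every n from 2 to 1000, five independent sets per n (4,995 datasets), and
records each sample SD. The SD converges to 1/rate ≈ 0.694 with
between-set spread shrinking as 1/√n, which is the visual argument for how
many tows a survey needs. `fit_exponential_rate` is the ML estimator
1/mean.

## Size spectra and coverage

Micro-debris enters with measured per-particle cross-sectional areas
(cm²); visually observed macro-debris items are assumed circular, area =
πd²/4 from the recorded longest dimension. Each item carries a numeric
density weight (1/area surveyed, m⁻²), and the spectrum reports per-bin
numeric density and share of total cross-sectional area over bins
log-spaced 10⁻³–10⁴ cm² by default. Coverage is 100 × (total debris area
in m²)/(surveyed area in m²). Where only size classes are known, coverage
is bracketed by evaluating every item at its class's lower and upper bound
diameter; the open ">30 cm" class uses a configurable cap, default 100 cm
— large enough to cover common large flotsam, small enough not to let a
single object dominate the maximum.

## Synthetic-data generator

The generator's purpose is structural fidelity, not oceanographic realism:

- **Concentration field.** A stationary Gaussian process on the 1-D cruise
  track with squared-exponential correlation (range in km; 0 = white
  noise) is normal-score transformed so the marginal is exactly
  exponential(rate), default rate 1.44. The copula choice is a stand-in:
  survey data pin down the skewed marginal but not the spatial covariance
  (the empirical debris variogram is artifact-prone), so the generator's
  range parameter is a knob for testing estimators, not an ocean estimate.
- **Wind coupling.** Observed concentration = latent × exp(−k·max(0, wind
  − wind_mean)), with per-tow wind ~ Normal(5, 2²) m/s truncated at 0
  (calm-to-moderate survey conditions) and decay k = 0.15 per m/s by
  default, enough to reproduce "high concentrations only in low wind"
  qualitatively.
- **Counts and masses.** Counts are Poisson(concentration × 774 m² tow
  area) — a 0.86 m mouth towed 900 m over ground; tow volume is area ×
  0.2 m. Plastic dry mass per tow is a Gamma sum of Exp(1 mg) per-particle
  masses; zooplankton dry biomass is lognormal with median 300 mg, σ_log
  0.8. Particle cross-sectional areas are exponential with mean 0.01 cm²,
  matching the modal-size observation for net-caught microplastic.
- **Sightings.** For each (size, colour) group, items are placed uniformly
  out to a 1000 m horizon at the group's true density, detected with
  half-normal probability (σ per group, larger for large/bright objects),
  then binned. Default densities total ~12 items/km², giving a few
  thousand sightings over a ~1300 km survey. The >600 m bin is generated
  and flagged.

What it does **not** emulate: transport and accumulation dynamics, diel
vertical migration, net avoidance/extrusion, observer fatigue or sea-state
effects on detection, correlation between macro- and micro-debris fields,
and the real (unknown) spatial covariance of debris. Passing tests
therefore demonstrate that the estimators recover the structure they
assume, not that the ocean has that structure.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to keep Monte Carlo error well
inside the asserted tolerances: 1000-replicate power cells checked against
a 10,000-replicate reference, 20 simulated fields of 400 stations for
variogram range recovery, 2000 binned sightings for σ recovery, and 200
surveys × 100 bootstrap replicates for CI coverage. All randomness flows
from explicit seeds (numpy `default_rng` / `SeedSequence` spawning);
pipeline reruns with the same config and seed are byte-identical.

## Known limitations

- The power analysis resamples the supplied base sample; its absolute
  power values inherit that sample's shape, and exponential surrogates
  understate the variance of heavier-tailed real surveys.
- Binned likelihoods lose information relative to exact distances; with
  six cells the hazard-rate shape parameter is weakly identified and the
  fit can be flat in AIC against the half-normal.
- The Gaussian copula cannot represent fields whose dependence differs in
  the upper and lower tails.
- Variogram fitting is WLS, not REML; no kriging or anisotropy.
- Coverage maxima depend directly on the configurable large-class cap.
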