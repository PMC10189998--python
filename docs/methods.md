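# Methods

## From trajectories to exploratory speed

A trajectory is a time-ordered series of planar positions (mm) with
strictly increasing timestamps (s), nominally sampled at 38 frames/s.
Per-frame speeds are Euclidean displacement over the time step. Tracking an
inactive animal still records small spurious position changes, so speeds
are filtered with a hysteresis rule before aggregation: a movement bout
opens at the first frame with speed ≥ `v_start` (default 0.6 mm/s) and
closes immediately before the first subsequent frame with speed <
`v_stop` (default 0.3 mm/s); a bout still open at the end of the series
closes there. The two-threshold rule prevents flicker at a single
boundary. No minimum bout duration is imposed, and the thresholds act on
raw per-frame speeds — an optional centered moving-average smoother exists
but defaults off, as does an optional recording-window trim.

The aggregation of frame speeds to one number per individual was a
genuinely open design choice. We pool as total within-bout distance over
total within-bout duration (a time-weighted mean over active periods)
rather than an arithmetic mean of frame speeds: the pooled form is
invariant to irregular frame intervals, and it is the natural reading of
"exploratory speed" as sustained active movement. An individual with no
bout gets a flagged missing value (NaN), never zero — zero would silently
bias any downstream fit. Linearity is exact: doubling all coordinates
doubles the result; doubling all time intervals halves it.

## Thermal performance curves

Five unimodal rate–temperature families are available: `gaussian`,
`modified_gaussian` (a Gaussian with free kurtosis; shape 2 recovers the
Gaussian), `quadratic`, a four-parameter `weibull`, and `pawar` — a
Sharpe–Schoolfield curve re-parameterised so the optimum temperature is an
explicit parameter and the maximum falls exactly at `T_opt` (an analytic
property the test suite verifies by dense-grid search). The Weibull and
modified-Gaussian forms follow the standard parameterisations of the
widely used TPC model collections; the Weibull is clipped to zero below
its lower support rather than returning NaN, which keeps the optimiser
in-domain. Temperatures are degrees C at every interface; the Kelvin
conversion (+273.15) is internal. Constants: k = 8.617·10⁻⁵ eV K⁻¹,
T_ref = 15 °C.

Default parameter bounds are deliberately wide for movement-speed data in
m/s: amplitudes in (0, 1], E in (0, 4] eV, E_h effectively in (0, ~34] eV,
T_opt in [0, 60] °C. The ordering constraint E_h > E is enforced by
optimising θ = log(E_h − E) internally, which turns it into a box
constraint; estimates and standard errors are reported on the natural
scale (the covariance uses a central-difference Jacobian with respect to
the natural parameters at the solution).

## Fitting and model selection

All fits are bounded trust-region nonlinear least squares
(`scipy.optimize.least_squares`, method `trf`, ftol = xtol = gtol =
1e-10), restarted from `n_starts` start vectors drawn uniformly from each
model's documented start ranges (production default 250 — generous for
3–5-parameter problems and still seconds of runtime). Start vectors are
drawn as one seeded block, so the best RSS is non-increasing in
`n_starts` under a fixed seed, and a fixed seed makes the whole fit
bit-reproducible. The best converged solution by RSS wins.

AIC uses the Gaussian-likelihood convention of R's `nls` objects,
`AIC = n ln(2π) + n ln(rss/n) + n + 2(p+1)`, where the +1 counts the error
variance; ΔAIC within a dataset is insensitive to this choice, but
absolute values are only comparable across software when the convention
matches. Ranking ties are broken by fewer parameters, then name. A model
that fails to fit keeps a row in the comparison with its error message
rather than aborting the comparison.

Intervals: Wald (estimate ± z·SE, with two-sided t p-values on n − p
degrees of freedom in summary tables) and case-resampling bootstrap
percentile intervals, each replicate refit from the original estimates as
the single start. The bootstrap is the default in CLI reports because the
sampling distributions of E_h and T_opt are visibly asymmetric at realistic
sample sizes. More than 20% replicate non-convergence attaches a warning.

## The combined allometric–thermal model

The headline model multiplies a power law in body mass (mg) with the
Sharpe–Schoolfield thermal factor; `a0` is then the speed of a 1 mg animal
at 15 °C. The objective is unweighted least squares on the natural speed
scale, not log-transformed — the conventional choice when fitting such
equations with `nls`-style tools, and the one under which the reported
parameters are conditional-mean parameters. At fixed temperature, ln v is
exactly linear in ln M with slope `b`; fixing b = 0 collapses the model
onto the pure TPC, and the test suite checks both routes land on the same
optimum. Identifiability guards reject data with a single distinct mass
(b unidentifiable) or a single temperature (thermal parameters
unidentifiable). Start ranges: a0 ∈ [1e-4, 0.5], b ∈ [−0.5, 1],
E ∈ [0.05, 2], E_h up to 8 with the gap constraint, T_opt ∈ [10, 40].

`predict_grid` evaluates the fitted surface on a mass × temperature grid
and warns — without refusing — when the grid extends beyond the studied
ranges (10–303 mg, 8–32 °C); the model has no information about, e.g.,
critical thermal limits outside them.

## Residual sensitivity analysis

To ask whether species identity or habitat preference explains residual
variation, a zero-intercept linear model `residual ~ 0 + group` is fitted
(statsmodels OLS on dummy coding): each coefficient is then literally that
group's mean residual, tested against zero with a pooled-variance
two-sided t-test. Pooled variance is the linear-model convention; note it
is anticonservative for groups whose residual spread is above average
(large-bodied groups under multiplicative noise). No multiplicity
adjustment is applied to the reported p-values; a Bonferroni column is
printed for transparency. With g groups tested unadjusted at α, the
chance of at least one false positive per study is of order 1 − (1−α)^g —
roughly a third for 8 groups — so a single flagged group in one dataset is
weak evidence by itself. Groups with one observation are reported without
SE/p and trigger a warning. A treatment-coded variant (intercept +
contrasts against the reference group) is available behind a flag.

## Synthetic data

The generator emulates the experimental design the pipeline targets:
125 individuals, 8 species assigned to log-spaced body-mass classes
spanning 10–303 mg (individual masses jitter log-normally within class,
sd 0.15 on the log scale, clipped to the range), 14 temperature levels
evenly spaced from 8 to 32 °C with individuals cycled across levels, and
habitat groups cycled over three labels. Where the real study's exact
species-by-level allocation would matter, it is not recoverable from
public information, so the generator uses these documented defaults.

Expected speed at each (mass, temperature) is the allometric–thermal
model at the carabid parameter estimates (a0 = 0.03, b = 0.12, E = 0.37,
E_h = 3.11, T_opt = 26.33); observed speed multiplies it by
log-normal(0, σ_log) noise with σ_log = 0.30 by default. The log-normal
form is a modelling choice (speeds are positive and the scatter looks
multiplicative); σ_log = 0.30 is a calibration that makes generated speeds
span roughly the observed 0.008–0.11 m/s range, not a measured quantity.
Gaussian additive noise and a per-species additive effect
(`species_effect_sd`, default 0) are available for sensitivity
experiments. Note E[v] = model · exp(σ_log²/2) under multiplicative
noise: the conditional mean sits ≈ 4.6% above the curve, which an
unweighted fit absorbs into `a0`.

Raw trajectories come from a two-state (move/pause) correlated random
walk: per-frame move speeds are mean-corrected log-normal around the
individual's target speed (CV 0.3), headings diffuse by wrapped-normal
steps (sd 0.3 rad/frame), pauses produce sub-threshold jitter below
0.3 mm/s, state transitions are per-frame Bernoulli (move→pause 0.005,
pause→move 0.02, i.e. bouts of ~5 s and pauses of ~1.3 s at 38 fps), and
the walk reflects off the 245 mm arena wall. Every generator is a
deterministic function of (configuration, seed).

What the generator does NOT emulate: wall-following (thigmotaxis),
within-individual temperature carry-over, species-specific thermal optima,
diurnal activity rhythms, or the unbalanced species-by-temperature
allocation of a real collection campaign. Passing tests therefore
demonstrate that the pipeline recovers the generating process under the
stated design — not that the statistical model is correct for any
particular real dataset.

## Validation experiments and problem sizes

`thermoallo.validation` packages the simulation experiments shared by the
test suite and `scripts/acceptance.py`:

- parameter recovery: 100 replicates of n = 125 at σ_log = 0.30; medians
  of all five parameters land within a few percent of truth (E_h, the
  hardest parameter, within ~10%).
- model ranking: with the Sharpe–Schoolfield family as the generating
  truth at the study's mean mass, it stays within ΔAIC ≤ 2 of the best of
  five models in ~84% of replicates.
- round trip: full walk → filter → fit replicates recover the allometric
  exponent with median bias well below 0.05.
- null calibration: with no injected species effect the residual test
  reports at least one significant species in ~18% of replicates — the
  expected family-wise consequence of 8 unadjusted tests (see above), not
  a pipeline bias.

Inside these experiments fits use 25 multistart draws (15 per model in
the five-model ranking); spot checks against the 250-start production
default reproduce identical optima on these 4–5-parameter problems, and
round-trip walks run 60 s of simulated recording per individual, long
enough that the filtered mean speed has stabilised. These sizes are the
package's own choices for routine validation; all are plain function
arguments and scale up freely.

## Known limitations

- The exploratory-speed aggregation (distance/time pooling) and the noise
  model are documented choices, not measured facts; alternatives
  (arithmetic frame-speed means, additive noise) are exposed but change
  numerical results slightly.
- Standard errors are Gauss–Newton approximations; near-degenerate fits
  (e.g. E_h at its bound) make them unreliable, which is why bootstrap
  intervals are the reporting default.
- The model pools species; it deliberately says nothing about
  species-specific optima, and predictions outside 10–303 mg / 8–32 °C are
  extrapolations the code only warns about.
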