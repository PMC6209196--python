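# Methods notes

This note records the models, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical choices a
maintainer would otherwise have to reverse-engineer.

## Telemetry processing

**Thinning.** 10-minute collars are thinned to the 30-minute grid anchored at
:00/:30 of the hour: each fix is assigned to its nearest grid slot and the
fix nearest the slot time survives (exact midpoints go to the earlier slot,
equidistant fixes to the earlier fix). Nearest-to-grid was chosen over
take-every-third because it is idempotent and robust to jittered fix times;
30-minute data pass through unchanged.

**Steps.** Speed is Euclidean distance on projected coordinates divided by
elapsed minutes. Steps whose interval falls outside 19.75–40.92 min (the
observed interval range of the original study; configurable) are dropped —
gaps are never interpolated. A step carries the camera day and day/night
label of its **ending** fix; either endpoint is defensible and the choice
only shifts labels by one 30-minute step at boundaries.

**Camera day.** Local time is UTC − 7 h (Mountain Standard Time; the study
window is January–March, so no DST transition occurs). Fixes strictly after
12:00 local roll to the next date; a fix at exactly noon keeps its date,
because the noon photograph is contemporaneous with it.

**Day/night.** Official sunrise/sunset (solar zenith 90.833°, i.e.
refraction-corrected) from the standard NOAA solar equations, evaluated at
the wolf's daily-centroid coordinates; `day` means sunrise ≤ t < sunset.
Latitudes beyond 66.5° are rejected — the day/night dichotomy breaks under
polar night. Accuracy is about a minute, far below the 30-minute step
resolution.

## Behavioral segmentation

The two-component normal mixture on pooled log10 speeds is fit by EM with a
deterministic initialization (means at the 25th/75th percentiles, equal
weights, pooled SD) so a given dataset always yields the same fit;
convergence is a log-likelihood change below 1e−8. Components are reported
slow-first. The rest/travel cutoff is the weighted-density intersection,
solved in closed form (quadratic in x for unequal SDs, linear for equal);
only the root strictly between the two means is accepted, and its absence
(possible under extreme weight imbalance) is an error suggesting a quantile
fallback rather than a silent guess.

Zero-distance steps have undefined log speed; speeds are floored at
0.01 m/min (the order of stationary-collar GPS jitter over 30 min) before
the log transform. The mixture is fit on speeds pooled across wolves — the
cutoff is meant to be one population-level labeling rule.

## Snow series and joins

Accumulation is the first difference of a camera's daily depth and is
undefined on the first day and after any gap: a multi-day depth change is
never spread over the gap, it is simply missing. Negative accumulation
(settling, melt) is kept as-is and can never trigger an event. The event
threshold is inclusive (≥ 5 cm/24 h). Wolf-days whose nearest camera lacks
that date's reading keep their row with missing snow values.
Nearest-camera ties break to the lexicographically smallest id —
deterministic and trivially documented.

## Windows and controls

The six date-based categories span two days before to three days after an
event. Where windows of two events overlap, the day goes to the nearer event
(ties to the earlier one); an event date is always `day_of_snowfall`. The
original analysis avoided overlap by capping the window length and states no
resolution rule, so this one is the package's own.

Controls are 3 dates per wolf per winter (read from the sentence structure of
the original design; a per-event mode would be a one-line change via
`n_controls`), drawn uniformly without replacement from dates at least 3 days
before or 4 days after *every* event of that wolf, one RNG substream per
wolf so adding a wolf never disturbs another's draw.

Rows with neither a category nor a snow depth are always omitted. The
modeling table keeps only the seven category levels, because all ten
candidate models must be fit to one common dataset; rows lacking snow depth
are additionally dropped before fitting for the same comparability reason.

## Mixed models

All fits are maximum likelihood, not REML, because AIC compares fixed-effect
structures. Reference levels are `day_of_snowfall` and `day`, making the
intercept the event-day daytime mean and every category coefficient a
contrast against the snowfall day.

*Travel speed* is an LMM on log10 m/min of travel steps with a by-wolf
random intercept and night slope (unstructured 2×2 covariance), fit with
statsmodels `MixedLM`. Optimizers are tried in the order L-BFGS, Powell,
Nelder-Mead and the best finite log-likelihood wins; fits whose profiled
likelihood diverges (singular covariance) are flagged non-converged and
excluded from selection tables with a warning.

*Time spent travelling* is a logistic GLMM with a by-wolf random intercept.
No installed Python package fits this by maximum likelihood, so the marginal
likelihood is implemented in-package with 9-point **adaptive** Gauss–Hermite
quadrature (nodes recentred at each wolf's posterior mode and rescaled by
its curvature — a strict refinement of the Laplace approximation).
Gradients treat the mode/scale as fixed, which is exact to quadrature
accuracy; they are verified against finite differences in the tests, and the
whole fit agrees with lme4's `glmer` (nAGQ = 9) to ~1e−3 on a frozen
cross-check fixture.

K counts fixed coefficients plus variance parameters: the LMM structure adds
2 variances + 1 covariance + the residual variance (so the null speed model
has K = 5), the GLMM adds 1 variance (null K = 2). This convention
reproduces every parameter count in the reference selection tables.

Model choice follows AIC with a parsimony rule: among models within 4 AIC
units of the leader, the smallest K wins (ties to smaller AIC) — extra
parameters that barely move the log-likelihood are treated as unsupported.

Bootstrap CIs are percentile intervals from parametric simulation: new
random effects (and, for the LMM, residuals) are drawn from the fitted
model, the model is refit warm-started, and failures are dropped and counted
(a rate above 10% attaches a warning). The reference analysis used 5,000
simulations; the default here is the same, while tests and the acceptance
script use 200 to keep runtimes reasonable — percentile endpoints at 200
draws are noisier but unbiased.

## Synthetic generator

The generator reproduces the study conditions: 17 wolves, 60 mid-winter
days, 30-minute fixes (10-minute optional), 14 cameras on a jittered grid
across an ~80 km square, initial depths around 50 cm. Events are Poisson
with 4 expected events per camera-winter (wolves in the denser year
experienced a mean of 4.3); half are study-wide and half per-camera
(`shared_event_prob = 0.5`, mirroring that about half the original events
were seen by a single wolf). Event accumulations are whole centimeters
drawn uniformly on 5–16 cm — the observed range; the distribution beyond
that range was not reported, so uniform is assumed. Settling noise is
±1 cm × the depth resolution with a slight negative drift and cannot reach
the 5 cm threshold, so injected events are exactly the detectable events.

Movement is two-state: each step is travel with probability given by a
logistic model in night and snowfall category (by-wolf random intercept)
whose default coefficients follow the published travel-probability pattern;
travel speeds are log10-normal around a linear model in the same covariates
(intercept 1.3 ≈ 20 m/min, night +0.107, category offsets from the
published speed contrasts), rest speeds are log10-normal jitter around
10^−0.3 ≈ 0.5 m/min. Positions advance speed × interval along a
persistent-heading walk with homing beyond 6 km, keeping each wolf near its
home range so the nearest-camera assignment is stable. One RNG stream per
module (cameras, tracks, pooled-speed sampler), all derived from the single
config seed: regenerating cameras never changes tracks.

**What it does not emulate,** and therefore what passing tests cannot show
about real data: state persistence (steps are conditionally independent
given covariates, so bout structure is absent — chosen so the ground-truth
travel fraction matches the inverse-logit of the linear predictor exactly);
terrain, linear features, pack cohesion, or home-range drift; GPS fix
failures and positional error; camera misreads or mid-season redeployments;
and any correlation between snowfall and wolf-independent covariates.
Recovery results on this generator validate the estimators, not the
field realism of the original data.

## Problem sizes in the test suite and acceptance script

Tests exercise reduced conditions chosen to keep the full suite in the
minutes range: the shared end-to-end fixture uses 5 wolves × 25 days; the
bootstrap-coverage check uses 50 replicates (30 logistic, 20 linear) of
6–8-wolf datasets at 200 bootstrap simulations each; the mixture-recovery
check uses 50,000 pooled speeds. The acceptance script runs the full 17 × 60
study conditions with 200 bootstrap simulations for the two selected models.

## Known limitations

- The GLMM supports the random-intercept structure the analysis needs, not
  arbitrary random-effect designs.
- The tangent-plane projection in the generator is adequate over ~100 km but
  not for continental-scale simulations.
- `MixedLM` interaction models on small datasets occasionally converge to
  singular random-effect fits; they are excluded from selection with a
  warning rather than silently ranked.
- Daily-distance summaries multiply speed by the nominal 30-minute interval
  rather than summing exact step distances, consistent with the
  standardized-interval design.
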