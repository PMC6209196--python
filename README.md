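# wolfsnow

Do snowfall events change how grey wolves (*Canis lupus*) move? Over a
boreal-forest winter, a wolf's GPS collar records a fix every 30 minutes and
remote cameras photograph snow poles every day at noon. `wolfsnow` is a
tested Python pipeline that takes those two data streams — or synthetic
stand-ins with the same statistical structure — all the way to mixed-model
selection tables describing how travel speed and the probability of
travelling respond to fresh snow.

It is written for movement ecologists and biologging analysts who want the
whole chain reproducible: step speeds, behavioral segmentation, snowfall-event
windows, and information-theoretic model selection under one seed.

## The method

1. **Steps and segmentation.** Fixes are thinned to a 30-minute grid and each
   consecutive pair becomes a *step* with speed `d / Δt` (m/min). Pooled
   log10 speeds are bimodal; a two-component Gaussian mixture

   `f(x) = w₁ φ(x; μ₁, σ₁) + w₂ φ(x; μ₂, σ₂)`

   is fit by EM and the intersection of the weighted component densities
   (solved analytically as a quadratic in `x`) is the rest/travel cutoff:
   steps at or above it are *travel*, below it *rest*. The original field
   study's cutoff, 1.65 m/min, ships as a constant.

2. **Snow cameras.** Daily accumulation is the first difference of each
   camera's depth series; a *snowfall event* is ≥ 5 cm in 24 h. Telemetry
   after local noon rolls to the next *camera day* so it aligns with the
   following noon photo. Each wolf-day takes the snow values of the camera
   nearest its daily centroid.

3. **Snowfall categories.** Days around each event are labeled
   `two_before … three_after`; per wolf, three random *control* dates are
   drawn at least 3 days before or 4 days after every event.

4. **Mixed models.** Ten candidate fixed-effect structures (all combinations
   of `snowfall_category`, `time_of_day`, `snow_depth`, plus the
   category-by-time interaction) are fit by maximum likelihood for two
   responses: a linear mixed model on log10 travel speed (by-wolf random
   intercept + night slope) and a logistic mixed model on the travel/rest
   label (by-wolf random intercept, adaptive Gauss–Hermite quadrature).
   Models are ranked by `AIC = 2K − 2 log L` with Akaike weights
   `wᵢ = exp(−Δᵢ/2) / Σⱼ exp(−Δⱼ/2)`; within 4 AIC of the leader the most
   parsimonious (smallest-K) model is selected, and its coefficients get
   parametric-bootstrap CIs, back-transformed as `10^β` (speed multipliers)
   or `exp(β)` (odds ratios).

## Worked example

```python
from wolfsnow import pipeline, synthetic

cfg = pipeline.RunConfig(
    simulate=True,
    sim=synthetic.SimConfig(n_wolves=17, n_days=60, seed=1),
    seed=1, n_boot=200, out_dir="demo_out",
)
res = pipeline.run_all(cfg)
print(f"cutoff: {res.cutoff_m_per_min:.2f} m/min")
print(res.speed_selection[["formula", "K", "logL", "delta_AIC", "weight"]].head(3))
print("selected:", res.speed_best["formula"], "/", res.travel_best["formula"])
```

prints (seed 1):

```
cutoff: 4.92 m/min
                                        formula   K         logL  delta_AIC    weight
0               snowfall_category + time_of_day  12 -2010.017678   0.000000  0.471658
1  snowfall_category + time_of_day + snow_depth  13 -2009.645868   1.256382  0.251656
2               snowfall_category * time_of_day  18 -2004.985523   1.935690  0.179183
selected: snowfall_category + time_of_day / snowfall_category * time_of_day
```

The fitted cutoff (4.92 m/min) is the density intersection for *this*
synthetic population — the generator's rest and travel modes are at
10^−0.3 ≈ 0.5 and 10^1.3 ≈ 20 m/min. The speed response selects the additive
category + time-of-day model and the travel-probability response selects the
category × time-of-day interaction, the same structures the generating
coefficients encode: snow-depth terms, simulated with zero effect, are
correctly rejected. `demo_out/` receives both selection tables, coefficient
tables with bootstrap CIs, per-category summaries, and a manifest with the
config hash.

A thin CLI wraps the same calls: `wolfsnow simulate`, `wolfsnow segment`,
`wolfsnow snow`, `wolfsnow run-all --seed 1`.

## Layout

- `src/wolfsnow/telemetry.py` — fixes, thinning, steps, centroids, day/night
- `src/wolfsnow/behavior.py` — speed-mixture EM, cutoff, classification
- `src/wolfsnow/snow.py` — depth series, events, nearest-camera joins
- `src/wolfsnow/windows.py` — snowfall categories, controls, analysis rows
- `src/wolfsnow/inference.py` — LMM/GLMM fits, AIC tables, bootstrap
- `src/wolfsnow/synthetic.py` — the data generator
- `src/wolfsnow/pipeline.py` — end-to-end orchestration
- `docs/methods.md` — modeling assumptions, defaults, and limitations
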