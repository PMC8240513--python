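# Methods

This note documents the models behind `canopygc`: what the simulator
generates, how the estimators and statistics are defined, the numerical
choices, and what the synthetic results do and do not say about real field
data.

## Trial and ground-truth model

The simulated experiment is a partial-replicate trial: `n_plots = 192` plots
on a 12 × 16 grid, `n_genotypes = 99`, each genotype sown on one or two plots
(93 duplicated, 6 singletons), giving mean replication
`nrep = 192/99 ≈ 1.94`. Plots are 6 m long with seven sown rows at 0.25 m
spacing and 0.4 m paths.

True ground cover is logit-normal:

```
logit(gc) = μ + g + r + c + e,
g ~ N(0, σ²g),  r ~ N(0, σ²row),  c ~ N(0, σ²col),  e ~ N(0, σ²ε)
```

Defaults (logit scale): μ = logit(0.45) = −0.2007, σ²g = 0.04,
σ²row = σ²col = 0.01, σ²ε = 0.033. The logit link keeps cover strictly in
(0, 1) and makes the variances interpretable; the genotype/residual split was
chosen once so that plot-level repeatability is ≈ 0.7
(σ²g / (σ²g + σ²ε/nrep) = 0.702), the mid-range of what early-season GC
trials achieve. Canopy height is `0.06 + 0.25·gc + N(0, 0.015²)` m, putting
the mean near 0.17 m — a tillering-stage canopy where a 10 cm height cut
misses prostrate leaves, so the height-based GC deliberately reads low.

## Sampling schedule

13 hourly events: 12:00–18:00 on day one, 07:00–12:00 the next morning. Each
event carries a solar-radiation value (MJ·m⁻²·h⁻¹) and a dew flag. The
default radiation curve is an idealized local clear-sky course —
(2.0, 2.1, 2.0, 1.7, 1.2, 0.6, 0.05) for the afternoon and
(0.15, 0.4, 0.8, 1.3, 1.8, 2.0) for the morning — with its minimum just
after sunset at 18:00 and low but usable light just after sunrise at 07:00.
This is a deliberate design choice: a radiation proxy measured tens of
kilometres away can read 0.0 at 07:00 while on-site dawn light is adequate
for photography, and the camera model here responds to local light. Dew is
flagged at 07:00 and 08:00 (allowed only when radiation ≤ 0.5). A packaged
CSV fixture (`canopygc/data/met_table.csv`) carries the measured hourly
weather of the two field campaigns this schedule emulates, with dew flags,
and can be loaded as an alternative schedule.

## Sensor models

**RGB camera (passive).** Each pixel is vegetation with probability `gc`.
Base colours: vegetation (60, 120, 55), soil (140, 110, 90) DN. Rendered
channel = `15 + base · E(L) + N(0, 8²)`, clipped to [0, 255], with exposure
`E(L) = L²/(L² + 0.2²)`. A per-image white-balance jitter `N(0, 4²)` DN is
added to the green channel. The jitter matters: pure contrast compression at
low light rescales the genotype and residual signal equally and would leave
repeatability untouched; real auto-exposure cameras instead become
frame-to-frame unstable in dim light, which is what destroys low-light
repeatability. At full light the jitter is negligible (soil misclassification
≈ 0.7%); at the 18:00 event (L = 0.05, contrast ≈ 3.5 DN against ≈ 12 DN of
noise) per-pixel classification approaches a coin flip and per-image GC
swings dominate, collapsing repeatability. The 15 DN dark floor keeps
zero-light frames as symmetric noise (P(G > R) ≈ 0.5) rather than clipped
black. Default images are 48 × 64 px, triggered every 1 m from a seeded
uniform phase, so 6 images per 6 m plot of which exactly 5 land in the 5 m
region.

**LiDAR (active).** Each of 1800 points per plot is vegetation with
probability `gc`. Intensity: vegetation N(2, 1.5²), soil N(30, 8²), clipped
to [0, 255] — the classic bimodal red-reflectance histogram with the valley
threshold fixed at 5 (no data-driven valley detection). Heights: vegetation
`h · Beta(2, 2)`, soil `|N(0, 0.02²)|` m (uneven ground). Under dew the
vegetation intensity mean shifts up by +6, pushing most leaf returns across
the 5 DN threshold; the simulator contract is pinned to the observed
direction of the field effect (reflectance-based GC drops under dew), not to
a radiometric mechanism, which remains unresolved. Heights are unaffected by
dew.

**Active NDVI.** Readings every `speed/rate` m (1 m s⁻¹, 10 Hz → 50 per 5 m
region): `0.10 + 0.80·gc + N(0, 0.02²)`, clipped to [0, 0.99]. The generator
ignores radiation and dew by construction — the property under study, not an
approximation.

Per-plot/per-event generators are seeded from
`SeedSequence([master_seed, plot, event_id])`, so any bundle is reproducible
in isolation and the full experiment is bit-deterministic.

## Estimators

Exact counting with strict inequalities (`VI > 0`, `intensity < 5`,
`height > 0.10 m`); boundary values classify as soil/ground, and
zero-denominator pixels (R = G = 0) are non-vegetation. Intervals are
half-open `[start, end)` in metres from the plot start. The ground reference
for heights is the 5th percentile of z within the region (minimum z, with a
warning, below 50 points); the testable contract is translation invariance
of GC_LiDAR^HT. Missing sensor streams produce flagged rows (NaN value,
`n_samples = 0`) — never silent zeros — because the statistics must
distinguish absent data from bare soil.

The cross-track region width is 1.25 m (5 inner rows ± half a spacing); field
reports describe it only as "approximately 1 m", so the geometry default is
documented here rather than asserted against any external value.

## Statistics

REML is fitted by direct optimization of the profiled restricted
log-likelihood: with variance ratios `γk = σ²k/σ²ε`,
`H(γ) = I + Σ γk Zk Zkᵀ`, the criterion
`log|H| + log|1ᵀH⁻¹1| + (n−1)·log(yᵀPy)` is minimized over `log γ`
(L-BFGS-B, bounds [−25, 12], fixed start γ = (1,1,1), ftol 1e−8), after
standardising y — REML is location-invariant and scale-equivariant, so this
is exact and only improves conditioning. σ̂²ε has the closed profiled form;
BLUPs are `γg Zgᵀ H⁻¹(y − μ̂)` rescaled. The fit is deterministic given the
data and is cross-checked in the test suite against lme4's solution of the
same crossed-random-effects model and against a grid-search evaluation of an
independently coded restricted likelihood.

No 2-D spline spatial surface is fitted: spatial trend is captured by row
and column random effects only. The simulator generates exactly row + column
structure, so the model is correctly specified for the synthetic data; on
real fields with smooth fertility trends a P-spline surface could absorb
additional residual variance, and repeatabilities computed here may differ
from spline-adjusted ones. `nrep` is `n_plots/n_genotypes`, not a harmonic
mean.

Correlations use `scipy.stats.pearsonr` with pairwise-complete deletion and
no multiple-testing correction; star boundaries are strict (`p = 0.05` earns
no star, `p = 0.0001` earns `***`). Correlation matrices are symmetric with
unit diagonal; pairs with fewer than 3 complete observations give missing
cells. Phenotypic correlations are computed on `μ + BLUP` (identical r to
BLUPs alone, since Pearson r is shift-invariant).

## Pipeline and outputs

`run_experiment` simulates event by event, estimates all four methods, fits
52 REML models (13 events × 4 methods), and emits CSVs only: GC table, event
summaries (mean ± sd), GC-versus-radiation pairings, variance components,
repeatability table, BLUPs, ICC matrices per method and phenotypic matrices
per event, each with a companion star matrix, plus a provenance JSON
(config + master seed + package version). Figures are intentionally not
produced; the CSVs are the contract and plots can be regenerated from them.
Any stage failure aborts with a stage-named error and removes partial
outputs.

## Problem sizes and runtime

Defaults were fixed once at desk scale: 48 × 64 px images (≈ 18k pixels per
plot-event), 1800 LiDAR points and 50 assigned NDVI readings per plot. The
trial structure (192 × 13 × 4 = 9 984 GC values) is full-size. A complete
experiment runs in ≈ 11 s on one CPU; the 20-seed qualitative suite and the
50-trial recovery study stay within a few minutes.

## What passing tests show — and what they don't

The simulator reproduces the *mechanisms* of interest (light-dependent
camera contrast, dew-shifted LiDAR reflectance, light/dew-invariant active
NDVI) with clean Gaussian/Bernoulli noise. It has no radiometric camera
model, shadows, wind or motion blur, no 3-D canopy occlusion, no GPS/IMU
positioning error, and the assignment loss that leaves real platforms with
only ~3 usable images per plot is not modelled (all 5 in-region images
survive). Dew in this simulator nearly erases the reflectance signal,
a stronger effect than fields typically show; the tested claims are
therefore directional (orderings, signs, ranges), not calibrated effect
sizes. Agreement of the qualitative suite with field behaviour supports the
analysis code, not the realism of any particular sensor's noise budget.

## Known limitations

- The REML optimizer handles the three-ratio problem; it is not a general
  mixed-model engine (no correlated effects, no heteroscedasticity).
- Repeatability standard errors and genetic correlations are out of scope.
- The height-based GC estimator inherits the 5th-percentile ground rule;
  on scans with no soil returns (full cover) it will misplace the ground.
- PLY support is ASCII, four properties (x, y, z, intensity) only.
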