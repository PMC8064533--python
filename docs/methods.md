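# Methods

## The estimator

The point-sampled intercept (PSI) method estimates the volume-weighted mean
particle volume v̄v = E[V²]/E[V] from 2D sections.  Test points on a uniform
grid hit particle profiles with probability proportional to profile area;
a section plane hits a particle with probability proportional to its height.
For each point landing inside a profile, the intercept l₀ is the connected
run of that profile through the point along the test-line direction, and

    v̄v = (π/3) · (1/n) · Σ l₀ᵢ³.

For spheres this is exactly unbiased for any section orientation, which is
why the simulator uses spheres: (4π/3)·E[R⁶]/E[R³] is available in closed
form (monodisperse, lognormal and two-point radius laws are supported), so
the entire chain — packing, sectioning, rasterization, field sampling, point
placement, intercept marching, estimation — can be validated against an
analytic value.  Real nuclei are irregular; PSI remains unbiased for them
only under isotropic line/section designs, so sphere-based validation
exercises the implementation, not the shape assumptions of any particular
tissue.

## Sampling design

* **Fields.** Square fields of area 10300.84 µm² (a 1000× field on the
  reference microscope geometry) on a regular lattice with one uniform random
  phase, visited in meander (boustrophedon) order; a field is retained iff
  its center lies inside the ROI polygon.  Fields flagged as excluded (the
  poor-focus analogue; exclusion is an input, since synthetic masks have no
  focus) are skipped before point placement.
* **Points and lines.** Each retained field carries a square point sub-grid
  with a uniform random phase and one line orientation θ ~ Uniform[0, π)
  shared by all its points — lines are randomly rotated between fields.  The
  default point spacing is side/3 (9 points per field); the stopping rule
  makes the estimate insensitive to this density, and denser grids
  (side/8–side/10) are used where a fixed intercept budget must be reached
  on sparse sections.
* **Stopping rule.** Fields are consumed until the target intercept count
  (default 75, with a warning below 50) is reached; the final field is always
  measured in full, so n may slightly exceed the target.  Points select
  profiles; they never clip geometry — a chord may extend beyond its field.
* **Intercepts.** Vector mode computes the disc chord 2√(ρ² − h²) in closed
  form.  Raster mode marches from the point along ±θ in steps of pixel/4 and
  refines each boundary crossing by bisection to pixel/64; a label change
  (including into a touching nucleus with a different label) terminates the
  run.  Touching same-label blobs would be measured as one profile — a
  limitation inherited from labeled-mask inputs.
* **Precision figure.** The reported CE is the relative standard error of
  the cubed-length mean, SD(l³)/(√n·mean(l³)).  It ignores the systematic
  (variance-reducing) structure of SUR sampling and is therefore a
  conservative precision proxy, labeled as such in outputs.
* **Replicates.** A case measurement is four independent runs (fresh field
  phases and angles) whose arithmetic mean is the case value, mirroring
  repeated operator sessions.

## Virtual tissue

Nuclei are non-overlapping spheres packed by sequential rejection sampling.
Two geometric choices matter:

* **Periodic exclusion.** Overlap tests use the minimum-image convention on
  the sampling box.  With hard walls, large spheres in a polydisperse mix
  accumulate near the boundary (more free volume there), which measurably
  depletes large nuclei around an interior section plane and biases v̄v low
  by ~1–2%; on the torus the packed process is exactly stationary.
* **Core inflation.** The center-sampling box extends 2·rmax beyond the
  requested core region on every side.  Sections and ROIs live in the core,
  so every disc that can contain a test point, and the full extent of every
  measurable chord, lies inside complete geometry — edge truncation cannot
  bias profile sizes or intercept lengths.  Rasters are rendered over the
  full inflated footprint for the same reason.

The packing fraction defaults to 0.15 (dense enough for realistic hit rates,
reliably packable under periodic exclusion); real tumor cellularity is not
characterized by the measurement design, so this is a free simulator
parameter.  The section plane is horizontal — valid for spheres, where
orientation is immaterial; ellipsoidal or irregular nuclei would require an
isotropic section design and are out of scope.  Pixel labels are resolved by
the nearest-disc-center rule where discs overlap (disjoint spheres yield
disjoint discs, so this matters only for externally supplied profile sets).
A sub-pixel disc that covers no pixel center is left unrendered with a
warning.  The per-seed estimate Σl³/n carries the usual O(1/n) ratio bias
(sections with more content yield both more and longer intercepts), so
multi-tumor validation pools intercepts across seeds before dividing.

## Synthetic cohorts

The generator emulates the structure of a 55-case grading study rather than
any real per-case data:

* **Grades.** True grade is two-tier (low ↔ G2/LG, high ↔ G3/HG), mixed
  39:16.  Per-grade v̄v is truncated-normal on the published summary numbers
  (low: mean 115.1, SD 28.8, range 38.6–175.7 µm³; high: 196.8, 65.5,
  102.1–363.3 µm³).  The truncated normal is a modeling choice over printed
  summaries, not a claim about the real data's distribution.
* **Replicates.** Four replicate measurements per case with multiplicative
  Gaussian noise, CV 5% by default — consistent with replicate concordance
  coefficients near 1.
* **Raters.** Three raters per scheme draw from per-rater confusion matrices.
  The default presets were *calibrated by simulation* to land Fleiss κ near
  the agreement levels typical of these schemes (≈0.3 for the 3-tier scheme,
  ≈0.45 for the 2-tier scheme); they are calibration artifacts, not measured
  rater properties.  Three-way disagreements are flagged unresolved and
  dropped from consensus-based stages rather than silently defaulted.
* **Outcome and survival.** A 30-case follow-up subset carries outcome
  OC0/OC1.  The default outcome law is logistic in v̄v (intercept −7.0,
  slope 0.04 µm⁻³, giving ≈20% OC1 over the default v̄v mixture, i.e. the
  6-of-30 design); a deterministic-threshold variant (τ = 125 µm³, optional
  flip noise) exists for exact-recovery tests.  Follow-up ends uniformly in
  12–27 months; OC1 events occur uniformly in (1, follow-up]; OC0 cases are
  censored at follow-up end.  Age ~ truncated N(8, 2.9²) years, sex 17:13
  F:M, margins truncated N(1.0, 0.5²) cm, breed sampled from the published
  30-dog roster; breed is carried in the schema but excluded from models
  (too many categories to analyze).

What passing tests on these cohorts shows: the statistics are implemented
correctly and the pipeline recovers constructions (thresholds, perfect
raters, null effects) exactly.  What they do not show: anything about real
tumors — replicate noise here is homoscedastic and multiplicative, raters
are conditionally independent given true grade, and outcome depends on v̄v
alone.

## Statistics

Youden's J (sensitivity + specificity − 1) selects the ROC operating cutoff,
reported as a value attained in the data with the ≥-cutoff-is-positive
convention; ties break toward the lower cutoff (favoring sensitivity).  The
criterion used by the original commercial analysis is not documented, so the
report metadata records this rule explicitly.  AUC uses the rank formulation
with ½ credit for ties; its 95% CI is DeLong's (the field standard; also not
documented in the motivating analysis).  Fleiss κ and the logistic fit come
from statsmodels (McFadden pseudo-R² = 1 − llf/ll₀), Welch/Wilcoxon/Friedman
from scipy, Kaplan–Meier and log-rank from lifelines; Lin's concordance
correlation coefficient uses population (1/n) moments per its original
definition.  (Quasi-)separation in the logistic fit falls back to BFGS and is
flagged and warned, never returned silently.  The pipeline's test choices are
fixed (Welch between grades, Wilcoxon between outcomes) rather than re-gated
on normality tests — reproducibility over automation; a χ²/Fisher contingency
utility is provided separately.  The logistic model defaults to
v̄v + age + sex, with margins available via configuration, since the two
plausible covariate sets are both defensible.  All pipeline stages fail
independently (a broken precondition marks the stage failed and the report
continues).

## Problem sizes and numerical choices

Oracle validations use 300×300×20 µm cores at 0.25 µm/pixel, ~32 independent
tumors per distribution and ~2,200 pooled intercepts — enough to resolve a
1% bias at 3 standard errors while keeping a full validation run in tens of
seconds.  The demo uses 0.4 µm pixels and six tumors.  Degenerate inputs are
errors, not defaults: empty intercept lists, single-class labels, constant
covariates and all-unanimous single-category rating matrices all raise
typed exceptions.  Raster coordinates are continuous µm with pixel centers
at (i+½)·pixel; a point exactly on a pixel boundary belongs to the
higher-index pixel.  All random draws are scale-free in form (uniform
fractions multiplied by physical lengths), which makes the estimator exactly
equivariant under coordinate rescaling: doubling all geometry multiplies v̄v
by exactly 8 at identical seeds.

## Known limitations

* Spheres only; no ellipsoid or irregular-shape support (would require
  isotropic-plane sampling for unbiasedness).
* Single-resolution rasters; no slide-pyramid or scanner-format ingestion.
* No H&E appearance, focus blur or segmentation: masks are assumed perfect,
  and field exclusion is an input flag, not a detector.
* No Cavalieri, disector or nucleator probes; no Cox models; no multiple-
  testing correction (none is part of the emulated analysis chain).
* The CE figure is a relative SEM, not a Gundersen-style systematic-sampling
  CE; it overstates the variance of SUR designs.
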