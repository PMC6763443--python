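# Methods

This note documents the models, parameter choices, and numerical decisions
behind `treemort`, and what the synthetic experiments do and do not
demonstrate about real airborne data.

## Synthetic landscape model

**Stand structure.** Trees are placed by sequential random sampling with
hard-core inhibition (candidates closer than `min_spacing_m`, default 4 m,
are rejected; a cell-grid keeps this O(n)). A requested density beyond the
circle-packing bound raises immediately with the achievable count; a
placement that stalls short after 200·n attempts records the shortfall.
Heights are i.i.d. truncated log-normal (μ = 2.85, σ = 0.45 on the log
scale, truncated to [5, 60] m), giving a right-skewed stand with most trees
10–25 m and a tail of emergents. Crowns are cones with radius 0.10 m per m
of height — a reasonable slenderness for drought-stressed conifers, and
narrow enough that crowns rarely overlap, which is the regime in which
local-maxima + watershed delineation is reliable. The default stand is
1500 trees on 300 × 300 m (≈ 167 trees ha⁻¹ above the 5 m floor).

**Environment.** Each environmental raster is a linear ramp plus a
Gaussian random field (white noise smoothed to a 50 m correlation length
and rescaled to the requested marginal SD). Maximum VPD spans 1.2–2.6 kPa
west to east. The temperature and precipitation anomaly fields are affine
functions of the VPD raster plus independent smooth noise whose variance is
solved analytically from the target correlation (for T = aV + e,
var(e) = a²var(V)(1/r² − 1)), so realized |r| lands within a few
hundredths of the targets 0.98 and −0.96. Soil available water capacity,
canopy cover, and slope ramp north–south with independent noise. Units:
kPa, % deviation from normals (ΔT, ΔPPT), mm (AWC), % (cover, slope).

**Hazard.** Annual per-tree death probability from local covariates, in
two forms: `logistic-status` (linear predictor on the log-odds scale) and
`linear-rate` (the probability itself linear, which makes the rate-scale
interaction model M = β₀ + β₁·Z·ΔENV exact). Probabilities are clamped to
[ε, 1−ε]; out-of-range linear-rate values are counted, not fatal. Death is
absorbing; a death in calendar year t is observed at the first acquisition
year ≥ t+1. Default acquisition years are 2009, 2010, 2012, 2014, 2016 —
five analysis years with the late-period two-year cadence that motivates
the rate = percent/2 convention. The default hazard combines a height
effect of 0.0231 per m with a VPD effect of 0.2833 per kPa on the log-odds
scale (odds ×1.26 per 10 m, ×1.12 per 0.4 kPa), with the intercept set for
a few percent annual baseline mortality.

**Imagery.** Crown pixels belong to the tree attaining the CHM maximum
there. The half-crown facing away from the sun azimuth (default 180°) is
shaded; dead/live status crosses with that to give four crown classes plus
background, each with a 4-band (R, G, B, NIR) Gaussian: dead crowns
red-shifted with depressed NIR, shading a roughly 2× radiance reduction,
diagonal covariances (SD 6). These defaults are deliberately
well-separated; classification difficulty can be dialed in by inflating
the covariances.

## Crown detection

Treetops are CHM pixels at or above 5 m that are maximal within a circular
window of radius max(1.5 m, 0.05·height) — taller trees get wider windows.
Equal-valued plateau pixels are resolved to the earliest pixel in row-major
order, so output is deterministic. Candidates are bucketed by integer
window radius and screened with one maximum-filter pass per bucket before
the exact (tie-aware) window check. Crowns come from a marker-based
watershed of −CHM (4-connectivity) masked at 5 m; catchments under
3 pixels merge into the neighbour with the highest shared-border CHM, and
mask components containing no marker are labeled as their own crowns so
the labels always partition the mask. The 5 m floor matches the smallest
analyzed height class; the window-radius rule is a package choice (the
field's variable-window conventions differ) and is configurable.

## Classification and dieback threshold

Per-class means and sample covariances (equal priors by default), with a
ridge of 10⁻⁶·trace/4 added to near-singular covariances. Pixels take the
argmax of Gaussian log-density plus log-prior; ties go to the lowest class
index; non-finite pixels fall to background and are tallied. The crown
dieback fraction is the mean of the binary dead raster over crown pixels,
and a crown is a dead tree when the fraction strictly exceeds 0.375. The
calibration grid (step 0.025) evaluates accuracy, false-positive and
false-negative rates at each threshold; near-ties in accuracy (within
0.005) are broken by minimal |FPR − FNR| — the "unbiased" reading of
threshold choice — then by the smaller threshold. Crowns are segmented
once (a single reference CHM) and classified per acquisition year.

## Temporal accounting

Status flickers from dead back to live are coerced to dead and counted:
with a single segmentation the absorbing-state rule is an explicit,
auditable correction rather than silent smoothing. Interval mortality
percent uses the susceptible pool at interval start (standing dead trees
never inflate later rates), annualized by the interval length; cumulative
mortality is referenced to the initial population, so
initial n = susceptible + cumulative dead holds at every acquisition. Rate
CIs use the normal approximation to the binomial. Height classes are
half-open ([5, 15), [15, 30), [30, ∞)) so every tree falls in exactly one.

## Driver models

Height and slope are log-transformed (log1p for slope, which can be 0),
temperature and precipitation enter as percent anomalies, and all columns
are z-standardized so coefficients are comparable; the transform metadata
is retained for exact unit back-conversion. VIF_j = 1/(1−R²_j) screens
collinearity at the conventional < 2 bar; the constructed VPD–T–PPT
collinearity trips it by design, motivating the reduced model that keeps
VPD and drops the anomalies. The logistic model is fit by IRLS (tolerance
10⁻⁸ on the coefficient step, 50-iteration cap, SEs from the observed
information); non-convergence or a coefficient passing ±30 raises with the
offending variable named, which catches complete separation. Odds ratios
are reported per SD and per physical increment (10 m, 0.4 kPa, 2.9 % ΔT,
4 % ΔPPT, 6.2 mm AWC, 17 % cover — conventional ≈1 SD increments for this
problem); for log-transformed covariates the per-increment ratio uses a
local linearization at the covariate mean and is flagged as such. The
report also notes whether the odds ratio can be read as approximate
relative risk (baseline mortality < 3%).

The rate model bins trees by all supplied covariates (default widths:
5 m height, 0.1 kPa VPD, 2 % anomalies, 5 mm AWC, 10 % cover, 5 % slope),
drops combinations under 25 trees (counted), computes
rate = dead/total/2 × 100 under the 2-year lag — capping any bin at
50 % yr⁻¹ by construction — and fits weighted least squares with tree
counts as weights. Weighting by n is a package decision; binned
proportions have variance ∝ 1/n, so it is the natural analogue of the
tree-level fit.

## Height-slope meta-regression

Within each environmental bin (default: 15 equal-width bins spanning the
1st–99th percentile), mortality rate per 5 m height bin is regressed on
the bin-center height, weighted by trees per bin; the slope is
β_MORTALITY-HEIGHT in % yr⁻¹ m⁻¹. The slope's σ is computed from the
binomial counting variance of each height bin's rate (shrunk proportion
(d+0.5)/(n+1)) propagated through the n-weighted estimator via the
sandwich formula, not from the fit residuals: with only ~10 height bins a
residual-based σ is so noisy that the inverse-variance weights of the next
stage become unstable and its nominal CIs undercover badly (observed ~82%
for a 2·SE criterion under a null hazard, vs 93–98% with the counting
variance). A consequence is that σ is strictly positive even for rates
that fall exactly on a line — it measures sampling noise, not residual
scatter.

Significant slopes (p < 0.05) are regressed on the environmental bin
center, weighted by 1/σ² (the figure-caption convention; 1/σ is also
implemented and the β₁ difference between schemes is logged, since the
literature uses both). The β₁ standard error uses the inverse-variance
(fixed-effects) form with the residual scale floored at 1, so between-bin
heterogeneity can widen but never narrow the interval. Weighted
R² = 1 − SSE_w/SST_w with the weighted mean in SST. Canopy cover is
additionally fit as two independent segments below/above 50% cover;
a side with fewer than 3 significant slopes is reported unfittable.

Note on the 2-year cadence: observing deaths over two years and dividing
by 2 attenuates high rates (1 − (1−p)² < 2p), so β₁ recovered under the
biennial design sits ~10–15% below the generating value at the default
effect sizes; the recovery studies that check unbiasedness therefore use
an annual observation interval, while the narrative analysis keeps the
biennial design to mirror the acquisition calendar.

## Problem sizes

The seeded recovery studies use 200,000 trees per replicate (odds-ratio
recoveries), 40,000 × 50 replicates (null-hazard coverage), and
500,000 × 10 seeds (interaction recovery); the rendered landscape analyses
use a 300 × 300 m domain at 0.6 m (500 × 500 pixels, 1500 trees). These
sizes give ≲1% Monte-Carlo error on the headline odds ratios while keeping
the full suite comfortably runnable on a single CPU.

## What the synthetic experiments do not show

The generator emulates the *structure* of the real inputs, not their
difficulty: crowns are exact cones with no overlap-driven occlusion,
spectra are Gaussian and temporally stable (no atmospheric or phenological
variation between years), environmental fields are smooth ramps, and the
hazard contains no spatial contagion (no beetle pressure, no
autocorrelated mortality patches). Passing tests therefore validate the
pipeline's correctness — detection geometry, classification optimality,
survivor-pool arithmetic, estimator calibration — and not its robustness
to sensor noise, registration error, or crown-form diversity in real
imagery. Species mixtures, ingrowth, and re-segmentation across years are
out of scope; spatial autocorrelation corrections and survival-time models
are deliberately not part of the driver analysis.
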