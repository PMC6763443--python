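# treemort

Tree-level drought-mortality analysis on synthetic forest landscapes.

During severe drought, tall conifers can die at much higher rates than
short ones, and the strength of that height dependence varies with local
climate and soil. Quantifying this from remote sensing takes a pipeline:
detect individual tree crowns in a canopy height model (CHM), classify each
crown live or dead from multispectral imagery, track crowns across repeated
acquisitions with a survivor-pool accounting, and model the drivers of
mortality. `treemort` implements that entire pipeline, together with a
seeded synthetic-landscape generator with known ground truth, so every
stage — detection, classification, temporal tracking, and the statistical
driver models — can be validated end to end without any proprietary or
downloaded data. It is aimed at remote-sensing ecologists and
biostatisticians who want a testable reference implementation of the
landscape mortality workflow.

## Methods at a glance

- **Synthetic landscapes** (`synthetic_forest`): trees placed by hard-core
  inhibition, truncated log-normal heights Z, conical crowns of radius
  0.10·Z; smooth environmental rasters (VPD_MAX, ΔT%, ΔPPT%, SOIL_AWC,
  COVER%, slope) with near-collinear VPD–temperature–precipitation
  structure (r ≈ 0.98 / −0.96); annual death draws from a configurable
  hazard, `logistic-status` (logit p = b₀ + b_Z·Z + Σ b_E·E + Σ b_ZE·Z·E)
  or `linear-rate` (p itself linear — the rate model
  M = β₀ + β₁·Z·ΔENV); 4-band imagery with sunlit/shaded × live/dead
  Gaussian spectral classes.
- **Crown detection** (`crown_detection`): treetops as circular-window
  local maxima of the CHM (window radius max(1.5 m, 0.05·Z)), crowns by
  marker-based watershed on the inverted CHM masked at the 5 m analysis
  floor; per-1 ha percent canopy cover.
- **Mortality classification** (`mortality_classification`): Gaussian
  maximum-likelihood pixel classification; crown dieback fraction = mean of
  the binary dead raster over crown pixels; a crown is a dead tree when its
  fraction exceeds 0.375 (threshold calibratable by grid search against
  validation labels, selecting the accuracy-maximizing, bias-balanced
  threshold).
- **Temporal tracking** (`temporal_tracking`): dead is absorbing; interval
  mortality = newly dead / susceptible pool; rate = percent / interval
  years (% yr⁻¹); height classes small [5, 15), medium [15, 30),
  large [30, ∞) m.
- **Driver models** (`driver_models`): z-standardized covariates (log
  height and slope), VIF collinearity screen (< 2), multivariable logistic
  regression by IRLS with odds ratios per SD and per physical increment
  (10 m, 0.4 kPa, …), a reduced model substituting VPD for temperature and
  precipitation, and a weighted linear model of binned mortality rate
  (rate = dead/total/2 × 100 under the 2-year observation lag).
- **Height-slope meta-regression** (`height_slope_analysis`):
  β_MORTALITY-HEIGHT (% yr⁻¹ m⁻¹) per environmental bin from
  sample-size-weighted fits of rate vs height, then 1/σ²-weighted
  regression of the significant slopes on the gradient (1/σ available);
  two-segment canopy-cover analysis split at 50%.

## Worked example

```python
import treemort as tm

scen = tm.SyntheticScenario(domain_size_m=(120, 120), n_trees=120, seed=7)
land = tm.simulate_mortality(tm.generate_landscape(scen))
chm = tm.render_chm(land)
tops = tm.detect_treetops(chm)
crowns = tm.segment_crowns(chm, tops)
print(len(land.trees), len(tops), int(land.trees.death_year.notna().sum()))
```

prints `120 117 26`: of 120 simulated trees, 117 are detected as distinct
crowns (three are short trees subsumed under taller neighbours) and 26 died
during the simulated drought. The full narrative analysis lives in
`analysis/01_simulate.py` … `06_height_slopes.py`; running them in order
writes rasters and tables under `results/`. On the default landscape
(seed 0) the sequence reports, among other things:

```
recall 0.965, precision 1.000 against generator apices
calibrated threshold 0.025 (accuracy 1.000; accuracy plateau 0.025-0.950 ...)
OR per 10 m height (full model): 1.284 [1.270, 1.298]
OR per 0.4 kPa VPD (reduced model): 1.125 [1.115, 1.135]
```

i.e. crown detection is near-perfect at the simulated stand density, the
dieback threshold is unconstrained when spectra are well separated (any
threshold on the wide plateau classifies perfectly), and the fitted odds
ratios recover the generating hazard (odds of death ×1.28 per 10 m of
height over a 2-year interval; ×1.13 per 0.4 kPa of maximum VPD).

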