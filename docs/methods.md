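# Methods

This note documents the models behind `pouchyoung`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer should know about.

## Growth model and age estimation

Pouch-young length traits are modelled as strictly linear in age,
*L = β₀ + β₁·t + ε*, with mm and weeks as the units throughout. Linearity
of crown–rump length over pouch life is well established across
dasyurids, bettongs and wallabies, and the packaged thylacine series
bears it out: the five litter means (26, 76, 89, 167, 214 mm at 1.5,
4.5, 5.25, 9.5 and 12 weeks) fit with R² ≈ 0.9993. No logistic or
Gompertz alternative is offered; over the 12-week pouch window the
linear model is the standard and the data cannot discriminate more
parameters.

Calibration and inference are deliberately deterministic. The historical
practice of manually "adjusting measurements to the regression line
until the fit is strong" is operationalised as: fit OLS lines on the
anchor litters per trait, inverse-predict each undated litter from every
available trait, average across traits, and snap to a rounding grid.
This reproduces the accepted stage ages without an under-specified
manual loop, and the combined-fit R² is reported so the user can see
whether the dated series stays on a tight line.

Parameters that matter:

* **Anchors** — default to the two litters whose ages are known
  independently of CRL: the neonate litter at 1.5 weeks and the oldest
  pup at 12 weeks (tooth-eruption evidence). Configurable; any trait
  with ≥ 2 anchors contributes a line.
* **Rounding grid** — 0.5 weeks, the resolution at which pouch-young
  ages are conventionally reported. Raw (unrounded) ages are always kept
  alongside.
* **Multi-trait combination** — the unweighted mean of the per-trait
  inverse predictions. How the historical CRL and head-length lines were
  combined into single ages was never written down; the unweighted mean
  is this package's documented choice, and the estimate records which
  traits fed it.

Known limitation: the A931 litter dates to 5.0 weeks from CRL alone,
while its accepted age is 5.25 weeks. The extra quarter week came from
head-length information that was never published as numbers; the package
reports the CRL-based estimate and does not guess. Negative inferred
ages (possible when extrapolating below the intercept) warn rather than
raise, since tiny lengths are legitimate inputs under extrapolation.

Singleton litters report a standard error of 0 with an explicit
`singleton` flag — keeping summaries total while preserving the
distinction from "all littermates identical".

## Allometry

Long-bone scaling is estimated on natural-log scale, ln L = a + b·ln C,
with RMA (standardized major axis) rather than OLS because length and
circumference are both measured with error; the RMA slope is
sign(r)·s_y/s_x, undefined at r = 0 (an error, not slope 0). Midshaft
circumference is computed from the two perpendicular midshaft widths as
π·(AP + ML)/2, i.e. a circular cross-section at the mean diameter.

Confidence intervals are case-resampling bootstrap over specimens,
default 10 000 resamples. The default interval is the percentile
interval (the convention of the classic RMA software this analysis
lineage used); a bias-corrected percentile variant is available via
`ci_method="bca"`. Resamples with zero spread on either axis have no
defined slope and are redrawn, with the redraw count reported —
discarding them silently would quietly shrink the effective bootstrap.
Degenerate-by-construction input (exactly collinear points) short-cuts
to a zero-width CI at the true slope.

Classification: with a CI, entirely above 1 → positive allometry,
entirely below 1 → negative, spanning 1 → isometry. Literature rows
without CIs are classified from the slope alone and flagged
`slope_only`. The packaged cross-taxon table stores the *published*
labels verbatim instead of recomputing them: several published rows lack
CIs, two of the published slope-only labels are mutually inconsistent
(opossum radius 0.85 "iso" vs possum humerus 0.887 "−"), and four of the
marsupial rows were computed from midshaft *width* rather than
circumference — comparability is annotated (`note="midshaft width"`),
not resolved. The published thylacine rows (slopes 1.198/1.403/1.241/
1.277 for humerus/radius/femur/tibia) are likewise packaged verbatim,
because the raw 13-stage length/circumference measurements behind them
were never published as numbers; the RMA implementation itself is
validated by the oracle identity and parameter-recovery tests below.

Proportion series use litter-mean lengths per stage, keyed by the stage
ages from the growth model. The crossover solver interpolates linearly
between stages and returns the earliest sign change of the difference,
solved exactly on the crossing interval; series that touch zero without
crossing return the touch age flagged `tangent`. On the published
fore/hindlimb values (60→65 and 55→68 %TL between 5.25 and 9.5 weeks)
the crossover falls at 7.90625 weeks — "about 8 weeks".

## Taxon rule

The diagnosis rule scores sacral count (2 thylacine / 3 other dasyurid),
caudal count (23–25 / 20–21) and epipubic ossification (absent /
present). Unknown characters are neutral; any conflict, or a count
outside both ranges, yields `indeterminate` with the per-character
evidence listed. Neonatal sacral counts are unreliable — the sacrum
ossifies late and very young thylacines can present an apparently
contrary count of three — so early-stage specimens should be entered as
unknown rather than counted; the rule does not attempt to resolve that
ossification-stage ambiguity.

## Synthetic data

`simulate_growth_series` draws litters of individual lengths as
β₁·t + β₀ + N(0, σ) on the mm scale; defaults are the thylacine
conditions (two-anchor calibration line slope 17.90 mm/wk and intercept
−0.86 mm, stage ages 1.5/4.5/5.25/9.5/12 weeks, litter sizes 4/3/1/1/1,
noise sd 1 mm — littermate spread in the real series is under 2.5 mm).
`simulate_allometric_bones` draws ln C uniform on a range and
ln L = a + b·ln C + N(0, σ), exported on the raw mm scale so the
pipeline exercises its own log transform; defaults are 13 stages, ln C
∈ (0, 4) (≈1–55 mm shafts, neonate to adult), log-noise 0.05 (matching
the >0.99 R² of the real fits) and a mildly positive exponent.

Noise is Gaussian and additive on the modelled scale (mm for growth,
ln-mm for allometry), matching the error model implicit in OLS/RMA.
Nonpositive draws are resampled, not clipped — clipping would bias slope
recovery — and the resample count is reported. Generators are pure
functions of their spec (which includes the seed).

What the generators do **not** emulate: allometric curvature or stage
heteroscedasticity, left/right asymmetry, missing-data patterns of real
museum series, litter effects beyond shared age, and ossification-stage
measurement censoring. Passing recovery tests therefore show the
estimators are correct under the stated error model, not that real
series meet that model.

## Validation strategy and problem sizes

* The RMA estimator is checked against the independent identity
  slope_RMA = slope_OLS / |r| (OLS from an external library) on 100+
  random datasets, to 1e-10, plus exact axis-swap reciprocality.
* Parameter recovery: exponents 0.8 / 1.0 / 1.4 at n = 200, log-noise
  0.05, recovered within ±0.05 and classified as negative / isometry /
  positive.
* Bootstrap calibration: empirical CI coverage at n = 13 over 200
  replicate datasets (10 000 resamples each, replicate index as seed),
  required within 5 points of the nominal 95%. Measured true coverage
  of the percentile interval at this n is ≈91% — the familiar mild
  undercoverage of percentile bootstraps at small n, inside the band.
* Age-recovery: 50 replicate noisy growth series (sd 2 mm) dated by
  two-anchor calibration, mean absolute error required < 0.25 weeks.

These problem sizes keep the full suite to a few seconds while holding
Monte-Carlo error well below the asserted tolerances.

## Numerical notes

* Zero spread is detected with `ptp == 0`, not `std == 0`: the mean of n
  identical floats can be off by one ulp, leaving a spurious std of
  ~1e-16 that would otherwise produce a garbage RMA slope on constant
  data.
* Rounding to the age grid is half-up (`floor(x/g + 0.5)·g`), so raw
  ages sitting exactly between grid points round toward the older age.
* Percentile CI bounds are clamped to include the point estimate,
  guarding quantile-interpolation excursions of order machine epsilon on
  near-degenerate data.
* R² of a fit with zero length variance is defined as 1 (a flat line
  through flat data), avoiding a 0/0 correlation.
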