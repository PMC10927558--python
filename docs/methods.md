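# Methods

`wetch4` reconstructs, end to end and against a verifiable synthetic truth,
the analysis chain used to upscale boreal–Arctic wetland methane fluxes from
site observations to gridded regional emissions and to attribute their
variability and trend to environmental drivers. This note documents the
models, the defaults and why they were chosen, what the synthetic scenes do
and do not emulate, and the numerical conventions.

## The analysis chain

1. **Inputs.** Weekly fields of eight drivers on a 0.5° grid — soil
   temperature (TS), air temperature (TA), gross primary productivity
   (GPP), air pressure (PA), precipitation (P), wind speed (WS), snow cover
   (SC) and soil water content (SWC) — plus a wetland map (total wetland
   fraction and bog/fen/marsh/tundra type fractions per cell) and a table of
   flux sites: eddy-covariance (EC) sites with weekly CH₄ flux series and
   chamber sites with a single period-mean flux over a stated window.
2. **Causal discovery (PCMCI).** Per wetland type, candidate parents
   (driver, lag ∈ 0..`max_lag`) of the weekly flux are screened by PC-style
   condition selection and confirmed by momentary-conditional-independence
   tests; the conditional-independence primitive is linear partial
   correlation with a two-sided t test.
3. **Causality-guided regression.** Per type, a small feed-forward
   regressor on the retained (driver, lag) features is trained on a
   mixed-frequency objective (weekly squared errors for EC records,
   window-mean squared errors for chamber records) plus a sign-consistency
   penalty tying the model's sensitivities to the causal-link signs. A
   20-member ensemble over independent random 80/10/10 splits provides the
   estimate (member mean) and its parameter uncertainty (member s.d.).
4. **Upscaling.** The ensemble is applied cell-wise; intensities
   (nmol CH₄ m⁻² s⁻¹) become per-cell emissions through the spherical cell
   area, wetland fraction and type partition, and aggregate to annual
   regional totals (Tg CH₄ yr⁻¹) for the whole domain, the Western Siberian
   and Hudson Bay lowland hotspot boxes, and the remainder.
5. **Attribution.** At the annual scale per cell: (i) the dominant driver
   of inter-annual variability by partial correlation of detrended
   anomalies, grouped into temperature {TS, TA}, GPP, water {P, SWC} and
   others {WS, PA, SC}; (ii) a factor-constant decomposition of the trend —
   an OLS model of annual flux on group indices is re-evaluated with one
   group frozen at its first-year value, so each group's contribution is
   exactly β·ΔX and contributions add to the full-model trend with no
   residual.

## Causal discovery details

* `max_lag` defaults to 8 weeks: the flux law's hysteresis (substrate lags,
  soil-thermal lags) acts on intra-seasonal scales; the planted synthetic
  lags are 0–3 weeks, so 8 leaves room to detect mis-specified structure.
  `alpha` defaults to 0.05; no multiple-testing correction is applied across
  links, so on null data roughly an `alpha` fraction of candidates would
  survive marginal screening — the sequential PC phase in practice retains
  far fewer (measured ≈0.017 at alpha 0.05).
* Condition selection tests each candidate, at every condition-set size
  p = 0, 1, 2, 3 (cap configurable), against the p strongest other surviving
  candidates, ordered by descending |partial correlation| with a fixed
  (driver, lag) tie-break. One subset per size keeps the procedure
  deterministic and fast; it is the standard practice for this family of
  algorithms.
* MCI conditions each candidate X(t−τ) on the flux's other candidate
  parents and on X's own PC-selected parents shifted by τ (lags 1..`max_lag`
  when selecting parents of a driver, so no contemporaneous loops).
  Multi-site panels concatenate per-site lagged samples; a lag never spans a
  site boundary.
* Degrees of freedom are n − |conditioning| − 2, plus an explicit
  `dof_loss` charge when the inputs were pre-processed (the attribution
  module passes 1 because its anomalies are detrended); without it the null
  significant-cell rate measured 7.2% at a nominal 5%.

## The learner and its objective

The regressor is a single-hidden-layer tanh network (16 units by default)
trained full-batch with Adam (lr 0.02). It is written in-package because the
objective is nonstandard in two ways:

* **Mixed-frequency loss.** Weekly records contribute pointwise squared
  errors; a chamber record contributes one squared error between the model's
  mean prediction over the record's window and the reported mean. Both are
  averaged together, so the loss reduces to ordinary MSE when all records
  are weekly.
* **Causal-guidance penalty.** For each causal link, the mean central
  finite-difference sensitivity of the prediction over a probe sample must
  agree in sign with the link's partial-correlation strength; violations
  enter as a squared hinge weighted by λ (default 0.1; features and targets
  are standardized internally so the two loss terms are on comparable
  scales, predictions are returned in physical units). Because the hinge is
  quadratic, the equilibrium under conflicting data sits at a vanishing —
  not exactly zero — violation.
* **Early stopping.** Validation loss (including the penalty, so a
  sign-violating fit cannot win model selection) with patience 20 epochs at
  1e-6 relative tolerance, after a 150-epoch warm-up; the warm-up stops the
  noisy first epochs of small validation sets from freezing the model near
  its initialization. Maximum 1500 epochs.

Validation skill is reported pooled across wetland types for each ensemble
member (R, MAE, and MAE normalized by the observed test-flux range), the
convention under which site observations of all types jointly validate the
upscaled product. Per-type skill for low-flux types is limited by the
observation noise floor, not by the model.

Three validation schemes are implemented: random 80/10/10 at the
observation level stratified by site (default; "observations" are individual
weekly points or single chamber means), leave-one-site-out, and a temporal
split holding out each site's final contiguous 20% of weeks.

## Units and aggregation conventions

* Intensity nmol CH₄ m⁻² s⁻¹; emission per cell per step =
  Σ_type intensity × area_type(m²) × Δt(s) × 10⁻⁹ mol/nmol × 16.04 g/mol;
  regional totals in Tg yr⁻¹ (10⁻¹² Tg/g). Cell areas use the spherical
  formula R²Δλ(sin φ₂ − sin φ₁), R = 6371 km.
* Weekly steps belong to the calendar month/year of their start date; annual
  totals sum the actual steps of each year (52/53-week years handled by true
  Δt, not a nominal 1/52).
* Trend = OLS on the annual series, two-sided t test on the slope; percent
  change = 100 × slope × (n_years − 1) / fitted value in the first year
  (fitted-value baseline, a documented convention). A constant series
  reports slope 0 with p = 1.
* The seasonal split fits each calendar month's annual series separately;
  monthly shares are slopes over the annual slope and sum to 1 exactly by
  OLS linearity.
* Ensemble member predictions are truncated at zero (fluxes are emissions);
  a single-member ensemble reports its uncertainty fields as missing, never
  as zero.

## Attribution choices

* Dominance is computed on flux *intensity*, not areal emission, so wetland
  area dynamics cannot masquerade as a driver.
* Cell-level significance of the winning driver uses a Šidák-corrected
  threshold p ≤ 1 − (1 − α)^(1/8): the winner is the largest of eight
  |partial correlations|, and an uncorrected α-level rule would flag ≈⅓ of
  null cells. With the correction the null rate measures 3–6% at α = 0.05,
  slightly conservative (the eight tests are not independent);
  `family_correction=False` restores the uncorrected rule. Ties in |ρ| break
  by the fixed order TS, TA, GPP, P, SWC, WS, PA, SC.
* Group regressors in the trend model are standardized within-group means
  (avoids the TS/TA collinear pair); the "others" group is included in
  Model_all by default so that "all temporally changing factors" drive the
  full model, and every group's percent contribution is reported so the
  contributions sum to 100% of the Model_all trend exactly.
* "Initial level" for the factor-constant counterfactuals is the first
  analysis year's value.
* With 7 conditioning drivers the dominance test needs ≥ 15 annual points
  (df ≥ 6); the default scene therefore spans two decades. Shorter scenes
  raise a configuration error rather than returning saturated ±1
  correlations.

## The synthetic scenes

The generator emulates the statistical structure the analysis assumes:
latitude-dependent seasonal cycles (pure functions of the step-start
calendar date, so monthly statistics carry no drift), weekly AR(1) anomalies
(coefficient 0.6) with GPP innovations positively coupled to TA and SWC to
recent P, linear decadal trends (defaults: +0.06 °C yr⁻¹ TS, +0.08 °C yr⁻¹
TA, +0.02 g C m⁻² d⁻¹ yr⁻¹ GPP — boreal-amplified warming and greening;
optionally restricted to chosen calendar months), and a per-type flux law

    intensity = baseline × q10^((TS(t−lag_T) − 10 °C)/10)
                × (1 + c_GPP × GPP(t−lag_G)) + noise,  truncated at 0,

with baselines 12–60 nmol CH₄ m⁻² s⁻¹ (fen/marsh > bog > tundra), Q10-like
sensitivities 2.2–3.0 and lags of 0–3 weeks. EC sites observe 1–3 years of
weekly intensity with 8 nmol m⁻² s⁻¹ observation noise; chamber sites report
one June–September period mean with 6 nmol m⁻² s⁻¹ noise (both
configurable; the observation-error magnitudes of real networks are not
well constrained, so these are knobs, not claims). A single `noise_scale`
multiplies every stochastic term; 0 gives a fully deterministic scene. One
master seed fans out to per-component streams, so each product can be
regenerated independently and identically.

The default desk scene is 10 × 20 cells (60–65° N, 60–70° E) over 2002–2022
(1044 weekly steps plus an 8-week spin-up that supplies lag history so the
analysis window has no masked steps). Wetland fraction is static by default
— the attribution design isolates emission-intensity change, and the
downstream code accepts a time-varying fraction where one is supplied.

What the scenes do **not** emulate: spatial autocorrelation of flux
responses beyond the wetland-type partition, retrieval physics of
satellite GPP, inundation/permafrost process dynamics, instrument-specific
EC error structure (gap patterns, u*-filtering), or non-Gaussian flux noise.
Passing recovery tests therefore demonstrates that the machinery is correct
and calibrated under its own assumptions — not that real-world skill will
match the synthetic numbers.

## Problem sizes used by the tests and the acceptance script

Unit and property tests run on panels of 50–4000 weeks and the desk scene;
calibration checks use 20–100 replicate seeds; the acceptance script runs
the full default desk scene (20-member ensemble) once and reports its main
quantities. These sizes were chosen so the whole suite documents the
behaviour of every stage at statistically meaningful sample sizes.

## Known limitations

* The conditional-independence test is linear; nonlinear dependence that
  leaves partial correlations near zero is invisible to the graph stage
  (the regressor itself is nonlinear).
* The guidance penalty constrains sensitivity *signs* only, not magnitudes
  or shapes.
* The PC phase caps condition sets at 3 (configurable); extremely dense true
  graphs could retain weak spurious parents.
* Percent-change trends use the fitted-first-year baseline; series whose
  fitted first-year value is near zero report unstable percentages (the
  slope and p-value remain well defined).
* NetCDF output uses the classic format (scipy engine); very large grids
  would need a chunked backend.
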