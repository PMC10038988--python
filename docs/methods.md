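# Methods

This note records the modelling choices behind `foodcast`, the defaults
and why they were chosen, and what the synthetic experiments do and do
not demonstrate.

## Target indicator

The unit of analysis is the daily prevalence of insufficient food
consumption in a first-level administrative area.  A household is
*insufficient* when its Food Consumption Score — the weighted sum of
0–7 consumption frequencies over eight food groups — falls at or below
the borderline threshold.  Boundary conventions are inclusive upper
bounds: poor iff FCS ≤ 21, borderline iff 21 < FCS ≤ 35.  The weights
(2, 3, 1, 1, 4, 4, 0.5, 0.5) and thresholds (21, 35) are the standard
operational convention; country programmes that use the 28/42 variant
can configure both, since national threshold choices are programme
policy rather than a property of the method.

Prevalence on day *t* is the weighted share of insufficient households
among those interviewed in the half-open window (t − d, t]: day *t*'s
interviews count towards day *t*, matching a daily-updated d-day
window.  The post-stratification weight of a household is the product
of its population and demographic weights.  *d* defaults to 28 days and
is a per-dataset parameter: it trades statistical stability of the
share against temporal resolution, and operational deployments choose
it per country.  Days whose window contains no interviews are missing
and are filled by linear interpolation *between* observations only;
leading and trailing gaps stay missing because extrapolation has no
support.  The companion coping indicator (share of households with
rCSI ≥ 19, threshold inclusive) is built identically.

## Permutation entropy

Ordinal patterns use the stable-argsort convention: a window of *m*
values spaced τ apart maps to the permutation that sorts it ascending,
with equal values keeping temporal order.  Tie handling must be fixed
deterministically because survey-derived prevalence series contain
plateaus; temporal-order tie-breaking is the common convention and
makes the symbolisation a pure function of the data.  Entropy uses the
natural log and is normalised by log(m!) so χ = 1 − H lies in [0, 1];
the base cancels under normalisation.

Defaults m = 3, τ = 1.  m = 3 keeps the pattern alphabet (6 symbols)
small relative to the shortest profiled window (10 days), so even short
windows can in principle visit every pattern; a guard rejects m with
m! greater than the smallest window.  τ = 1 because the profile is about
day-to-day structure on contiguous stretches.  The profile draws 1000
window placements per series and length (uniformly without replacement
when enough distinct starts exist, with replacement otherwise) over
lengths 10–100, and aggregates mean and interquartile range of χ across
windows and areas.  Note that windowed χ at short lengths is biased
upwards for any series — few patterns fit in a short window — so the
profile's *decay* with window length, and differences *between* series
at a fixed length, are the meaningful readings, not absolute levels.

## Exogenous features

All drivers are aggregated causally: the value dated *t* uses only
information from (t − d, t] or earlier, so any feature lagged by
ℓ ≥ 0 days is measurable at the reference date.

* **Conflict fatalities**: event-level fatality counts summed per area
  over the same trailing d-day window as the target, so both describe
  the same history.
* **Market prices**: monthly staple prices per market, divided by the
  *expanding* mean of that market's own history (unit-free and causal —
  a fixed-period mean is available as an option), then averaged across
  the area's markets and forward-filled to days.
* **Rainfall**: dekadal (10-day) totals in mm; anomalies are
  percent-of-average, 100 × (trailing sum over 3 or 9 dekads) /
  (historical dekad means over the same dekads of the year) — 100 means
  normal.  Zero-baseline dekads give missing anomalies with a warning
  rather than an arbitrary value.
* **NDVI**: dekadal index and its single-dekad percent-of-average
  anomaly; vegetation already integrates past rainfall, so no
  multi-dekad window is applied.
* **Ramadan**: the number of observance days inside the trailing d-day
  window — zero outside, ramping between 1 and min(d, length) during
  and shortly after, mirroring how much of the consumption-recall
  window the observance overlaps.
* **Statics and calendar**: population, area, latitude, longitude,
  waterways size; day/month/year of the *forecast* date.

Collinearity screening happens within the weather category (the only
one with several variables): Pearson correlations on pairwise-complete
native-resolution (dekadal) values; while any pair exceeds |r| = 0.45,
the member of the worst pair with the larger mean absolute correlation
to the surviving rest is dropped (alphabetical tie-break).  The
remaining design is checked with VIF_j = 1/(1 − R²_j); values at or
above 3 are flagged.  Screening on native resolution avoids the
artificial correlation inflation that daily repetition of dekadal
values would introduce.

## Forecasting

One XGBoost regressor per horizon h = 1..30 (squared-error objective,
histogram trees, missing values routed natively).  Separate models per
horizon sidestep multi-output boosting and let each horizon select its
own structure.  Evaluation splits are the last *k* complete calendar
months (default k = 5): for each split, forecasts launch from the day
before the test month — the horizon-h test points are each area's
prevalence h days into the month — and training uses only rows whose
*target* date precedes the month.  Consequently everything the test
predictions touch is dated before the test month, which the test suite
verifies by corrupting all later data and asserting bit-identical
predictions.

Within a split's training region, the first 80% of rows (time-ordered
by reference date) train each hyper-parameter candidate and the last
20% score it by MSE; the boosting-round count comes from early stopping
(cap 400, patience 20) on that validation block.  The winning
configuration is refit on the full training region with the validated
round count before testing — refitting uses all pre-test information
and is the default (switchable via `refit=False`).  The default grid
crosses max_depth {3, 5, 7}, learning rate {0.05, 0.1} and subsample
{0.8, 1.0}; scaled-down experiments use a single mid-grid candidate
(depth 4, rate 0.1, no subsampling).  Feature selection operates at the
level of configured lag-set presets rather than per-feature search,
keeping the search space bounded and interpretable.  Predictions are
clipped to [0, 1] because the target is a prevalence.  One seed
controls learner randomness; fits are deterministic given it.

The benchmark is persistence: the last observed value at or before the
launch date, for every horizon.  Scoring pools all areas of a split per
horizon: R² = 1 − SS_res/SS_tot against the test-set mean, MSE plain;
zero-variance test sets yield missing R² with a warning.  ΔMSE =
MSE_naive − MSE_model is positive when the model wins.

## Synthetic scenarios

The generator reproduces the statistical setting the analysis assumes,
not any particular country.  Latent prevalence per area follows a
logistic-linear model: intercept −0.55 plus standardised driver effects
(fatality window sum +0.30, normalised price +0.45, 1-month rainfall
anomaly −0.15, NDVI anomaly −0.20, each lagged 30 days; Ramadan counter
−0.15, contemporaneous since the calendar is known) plus AR(1) noise
(ρ = 0.97, innovation sd 0.035).  The signs encode conflict and price
shocks raising food insecurity and good rains, green vegetation and
Ramadan consumption lowering it; the 30-day driver lag reflects
delayed transmission of shocks into consumption and means horizon-30
forecasts can in principle observe every relevant driver value.  The
default scale — 20 areas × 1340 days, window 28 — mirrors the largest
real monitoring setting; the magnitudes place ≥ 90% of area-days in the
0.15–0.65 prevalence band, matching the 20–60% range the real series
occupy, and the AR(1) component gives the series the slow wandering
that makes short-horizon persistence strong.

Drivers: fatalities are Poisson (rate 0.15/day) interrupted by rare
episodes (entry probability 0.01/day, geometric mean duration 7 days,
rate 6/day) — overdispersed with burst structure; rainfall is Gamma
around a sinusoidal seasonal dekad curve whose exact values double as
the "historical average" baseline; NDVI is a smoothed one-dekad-lagged
response to rainfall; prices follow a per-market geometric random walk
with occasional upward jumps; 2018–2022 Ramadan dates are built in.

Households are sampled class-first: insufficient with probability equal
to the latent prevalence of the area-day, then food-group frequencies
drawn from class-specific binomial proposals and redrawn until the FCS
classification matches the drawn class.  This guarantees the household
class marginal equals the latent prevalence exactly, making indicator
recovery exactly testable.  Coping frequencies are higher on average
for insufficient households so the coping indicator co-moves with the
target.  Post-stratification weights are i.i.d. unit-mean lognormal
(σ = 0.3) — the weight distribution of the real surveys is not public,
so this is a modelling choice: positive, right-skewed, mean-one, mild
design effect.  An optional gap fraction removes whole area-days to
exercise interpolation.  All randomness derives from one integer seed
via independently spawned sub-streams.

What the generator does *not* emulate: spatial correlation between
areas beyond shared seasonality, panel structure or respondent-level
persistence in surveys, mode/selection bias, regime changes in driver
effects, or any attempt to fit real country data.  Passing tests
therefore show the *machinery* is correct and that the method recovers
known structure under its own assumptions — not that real series are
predictable to any particular accuracy.

## Experiment sizes

The bundled experiments use sizes chosen to place the learner on both
sides of its data-hunger threshold while keeping runs desk-scale: the
skill-recovery experiment runs 20 areas × 1300 days with 3 monthly
splits, horizons 1 and 28, and the single-candidate grid; the learning
curves use a 16-area × 1300-day scenario subset to 4 nested lengths
(160–1300 days at all areas) and 4 nested area counts (3–16 areas at
520 days, scored on a common 3-area test population so test-set
composition does not confound the curve).  With these sizes the model
ties persistence at 1 day, beats it clearly at 28 days, and its
advantage grows with training points — the qualitative pattern expected
when secondary information matters; the advantage saturates beyond
roughly ten thousand training points on these scenarios.  The common
test population is a deliberate departure from simply scoring each
subset on its own areas: without it, which areas happen to be in the
subset dominates the curve.

## Known limitations

* Prevalence windows overlapping d days induce autocorrelated
  measurement error; the forecaster sees the smoothed series, and no
  correction for shared-window overlap between features and target at
  horizons below d is attempted (the real indicator has the same
  property).
* The learning-curve "number of training points" counts area-days
  available before the first test month; it does not account for the
  information overlap of adjacent rolling-window days.
* VIF is computed on complete rows only; with heavily missing features
  the screen describes the complete-case subsample.
* Forecast paths launch once per split (the day before the test month),
  mirroring an operational monthly re-forecast; per-day rolling origins
  within the month would multiply test points but blur the
  no-future-information boundary the evaluation is built around.
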