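# foodcast

Forecastability analysis of sub-national food insecurity: from household
survey records to daily prevalence series, intrinsic-predictability
profiling, and 1–30-day-ahead forecasts benchmarked against persistence.

## The problem

Humanitarian monitoring systems run daily remote phone surveys in
crisis-affected countries and publish, per first-level administrative
area, the prevalence of people with *insufficient food consumption*.
These series are noisy and irregular, yet operational decisions depend
on where the situation is heading over the next days and weeks.  This
package implements that analysis chain end to end:

1. **Indicator construction** (`foodcast.indicators`).  Each surveyed
   household gets a Food Consumption Score,
   `FCS = Σ_g w_g · f_g`, a nutrition-weighted sum of 7-day consumption
   frequencies over eight food groups (default weights
   2, 3, 1, 1, 4, 4, 0.5, 0.5; poor ≤ 21 < borderline ≤ 35 <
   acceptable), and a reduced Coping Strategy Index
   `rCSI = Σ_s v_s · c_s` over five coping behaviours (weights
   1, 2, 1, 3, 1; crisis coping at rCSI ≥ 19).  The daily area-level
   prevalence is the post-stratification-weighted share of
   poor-or-borderline households interviewed in the trailing *d* days
   (default d = 28), with interior gaps filled by linear interpolation.

2. **Intrinsic predictability** (`foodcast.predictability`).  Windows of
   *m* consecutive values are symbolised into ordinal patterns
   (Bandt–Pompe); the normalised permutation entropy
   `H = −Σ_π p_π log p_π / log(m!)` yields the predictability
   `χ = 1 − H`, profiled over window lengths 10–100 days with many
   random window placements per series.

3. **Forecasting** (`foodcast.features`, `foodcast.forecast`).  Thirty
   horizon-specific XGBoost regressors predict prevalence 1–30 days
   ahead from lagged prevalence and coping series, conflict fatalities,
   normalised market prices, rainfall/NDVI and their percent-of-average
   anomalies, a Ramadan-overlap counter, static area attributes and
   calendar identifiers — all screened for collinearity (pairwise
   |r| > 0.45 pruning, VIF check) and constrained so that no feature
   looks past the forecast launch date.  Evaluation uses time-ordered
   monthly splits with an 80/20 time-ordered train/validation stage, and
   every model is benchmarked against the *naive persistence* forecast
   (the last observed value, at every horizon) via R² and
   ΔMSE = MSE_naive − MSE_model.

4. **Synthetic scenarios** (`foodcast.synth`).  A seeded generator
   produces multi-area datasets with the assumed structure — latent
   prevalence in the 20–60% band driven by lagged conflict, price,
   weather and Ramadan effects plus AR(1) noise, and household surveys
   sampled from it — so the whole chain is testable against a known
   ground truth without any external data.

## Worked example

```python
from foodcast.synth import ScenarioConfig, generate_scenario, daily_driver_features
from foodcast.indicators import rolling_prevalence, interpolate_gaps, fcs_insufficient, rcsi_crisis
from foodcast.predictability import predictability_profile
from foodcast.features import LagConfig
from foodcast.forecast import forecast_experiment, REDUCED_GRID
from foodcast.evaluate import score_split, delta_metrics

cfg = ScenarioConfig(n_areas=10, n_days=700, households_per_day=25, seed=0)
drivers, latent, surveys = generate_scenario(cfg)

d = cfg.rolling_window_d
target = interpolate_gaps(rolling_prevalence(surveys, d, fcs_insufficient(), index=cfg.index))
rcsi = interpolate_gaps(rolling_prevalence(surveys, d, rcsi_crisis(), index=cfg.index))

profile = predictability_profile(target, window_lengths=[10, 30, 60, 100], n_samples=500, seed=0)
print(profile.round(3).to_string(index=False))

daily = daily_driver_features(drivers, cfg, cfg.index)
lags = LagConfig(target=(0, 1, 3, 7, 14, 21, 28), rcsi=(0, 7, 14, 28), drivers=(0, 7, 14, 30))
preds = forecast_experiment(target, rcsi, daily, drivers.statics, lags=lags,
                            horizons=[1, 7, 28], k=3, hyper_grid=REDUCED_GRID, seed=0)
scored = delta_metrics(score_split(preds))
print(scored.groupby("horizon")[["r2_model", "r2_naive", "delta_mse"]].mean().round(4))
```

Output:

```
 window_length  mean_chi   q25   q75  n_windows
            10     0.467 0.226 0.589       5000
            30     0.283 0.119 0.402       5000
            60     0.188 0.103 0.259       5000
           100     0.156 0.104 0.205       5000
         r2_model  r2_naive  delta_mse
horizon
1          0.9966    0.9970    -0.0000
7          0.9464    0.8733     0.0009
28         0.7196   -0.4094     0.0124
```

Reading it: the prevalence series carry little exploitable memory — mean
χ falls below 0.2 once windows reach two months, i.e. the series look
nearly as irregular as noise over those spans.  One day ahead,
persistence is essentially unbeatable (R² ≈ 0.997 for both).  Four weeks
ahead, persistence collapses (R² < 0) while the driver-informed model
still explains ~72% of the cross-area variance, a mean MSE advantage of
0.012 — exploiting secondary information (conflict, prices, weather,
Ramadan) that the target's own history does not contain.

## Command line

Every stage is also a CLI step writing plain CSV into a run directory
(resumable; `manifest.json` records seeds and output hashes):

```bash
foodcast all --config scenario.yaml --out runs/demo --seed 7
foodcast predictability --out runs/demo   # re-run a single stage
```

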