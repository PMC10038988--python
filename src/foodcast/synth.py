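"""Seeded synthetic multi-area scenarios for the full analysis pipeline.

The generator emulates the statistical setting the pipeline assumes: a
handful of first-level administrative areas observed daily over several
years, each with a latent prevalence of insufficient food consumption in
the 20–60% band, driven by lagged exogenous shocks — episodic conflict
fatalities, seasonal rainfall and the vegetation response to it, a
drifting staple-price index, and the Ramadan observance — plus a slow
AR(1) disturbance.  Household surveys are then sampled from the latent
prevalence so that the indicator pipeline can be validated against a
known ground truth.

Everything is a deterministic function of (config, seed); sub-streams
for each component are spawned from one root seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from . import features
from .indicators import (
    COPING_COLUMNS,
    FOOD_COLUMNS,
    FcsScheme,
    RcsiScheme,
    compute_fcs,
)

__all__ = [
    "ConfigurationError",
    "ScenarioConfig",
    "DriverBundle",
    "LatentPrevalence",
    "DEFAULT_RAMADAN_INTERVALS",
    "generate_drivers",
    "generate_latent_prevalence",
    "sample_household_surveys",
    "generate_scenario",
]


class ConfigurationError(ValueError):
    """A scenario configuration field is invalid."""


#: Approximate Ramadan observance periods for 2018-2022 (Gregorian dates).
DEFAULT_RAMADAN_INTERVALS = (
    (date(2018, 5, 16), date(2018, 6, 14)),
    (date(2019, 5, 6), date(2019, 6, 4)),
    (date(2020, 4, 24), date(2020, 5, 23)),
    (date(2021, 4, 13), date(2021, 5, 12)),
    (date(2022, 4, 2), date(2022, 5, 1)),
)

#: Effects of standardised lagged drivers on the latent logit.  Signs:
#: conflict and price shocks push prevalence up, good rains and greener
#: vegetation pull it down, Ramadan consumption pulls it down.
DEFAULT_DRIVER_COEFFICIENTS = {
    "fatalities": 0.30,
    "price": 0.45,
    "rainfall_anom_1m": -0.15,
    "ndvi_anom": -0.20,
    "ramadan": -0.15,
}

#: Days of driver history generated before the scenario start, so that
#: anomalies, rolling windows and lagged effects are defined from day 1.
_BUFFER_DAYS = 130


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic multi-area scenario.

    The default scale mirrors the largest real monitoring setting the
    pipeline targets: 20 areas observed daily for 1340 days, with a
    28-day prevalence window.
    """

    n_areas: int = 20
    n_days: int = 1340
    start_date: date = date(2018, 6, 1)
    households_per_day: int = 25
    rolling_window_d: int = 28
    intercept: float = -0.55
    driver_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRIVER_COEFFICIENTS)
    )
    driver_lag: int = 30
    ar1_rho: float = 0.97
    noise_sd: float = 0.035
    ramadan_intervals: tuple[tuple[date, date], ...] = DEFAULT_RAMADAN_INTERVALS
    # conflict process
    burst_rate: float = 0.01
    burst_mean_duration: float = 7.0
    base_fatality_rate: float = 0.15
    burst_fatality_rate: float = 6.0
    # survey sampling
    weight_sigma: float = 0.3
    gap_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> "ScenarioConfig":
        checks = {
            "n_areas": self.n_areas >= 1,
            "n_days": self.n_days >= self.rolling_window_d,
            "households_per_day": self.households_per_day >= 1,
            "rolling_window_d": self.rolling_window_d >= 1,
            "driver_lag": self.driver_lag >= 0,
            "ar1_rho": 0.0 <= self.ar1_rho < 1.0,
            "noise_sd": self.noise_sd >= 0.0,
            "burst_rate": 0.0 <= self.burst_rate <= 1.0,
            "burst_mean_duration": self.burst_mean_duration >= 1.0,
            "base_fatality_rate": self.base_fatality_rate >= 0.0,
            "burst_fatality_rate": self.burst_fatality_rate >= 0.0,
            "weight_sigma": self.weight_sigma >= 0.0,
            "gap_fraction": 0.0 <= self.gap_fraction < 1.0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ConfigurationError(
                    f"invalid configuration field {name!r} = {getattr(self, name)!r}"
                )
        unknown = set(self.driver_coefficients) - set(DEFAULT_DRIVER_COEFFICIENTS)
        if unknown:
            raise ConfigurationError(
                f"unknown driver_coefficients keys {sorted(unknown)}; "
                f"known drivers: {sorted(DEFAULT_DRIVER_COEFFICIENTS)}"
            )
        for start, end in self.ramadan_intervals:
            if end < start:
                raise ConfigurationError(
                    f"invalid configuration field 'ramadan_intervals': "
                    f"interval ({start}, {end}) ill-ordered"
                )
        return self

    @property
    def index(self) -> pd.DatetimeIndex:
        """The scenario's daily calendar."""
        return pd.date_range(pd.Timestamp(self.start_date), periods=self.n_days)

    @property
    def areas(self) -> list[str]:
        return [f"area_{i:02d}" for i in range(self.n_areas)]


@dataclass(frozen=True)
class DriverBundle:
    """All exogenous inputs of one scenario.

    Daily/dekadal/monthly frames cover a buffer period before the
    scenario start so trailing windows and lags are defined everywhere.
    """

    events: pd.DataFrame  # long: area_id, date, fatalities (>0 rows only)
    fatalities_daily: pd.DataFrame  # wide daily counts (incl. zero days)
    rainfall_dekads: pd.DataFrame  # wide, index = dekad start dates, mm
    rainfall_baseline: pd.DataFrame  # wide, index = dekad-of-year 1..36
    ndvi_dekads: pd.DataFrame
    ndvi_baseline: pd.DataFrame
    prices: pd.DataFrame  # long: area_id, market, month, price
    ramadan_calendar: pd.DatetimeIndex
    statics: pd.DataFrame  # index area_id; population, geometry, waterways

    def validate(self) -> "DriverBundle":
        if (self.fatalities_daily < 0).any().any():
            raise ValueError("fatality counts must be nonnegative")
        if (self.rainfall_dekads < 0).any().any():
            raise ValueError("rainfall must be nonnegative")
        nd = self.ndvi_dekads
        if ((nd < -1) | (nd > 1)).any().any():
            raise ValueError("NDVI must lie in [-1, 1]")
        if (self.prices["price"] <= 0).any():
            raise ValueError("prices must be positive")
        return self


@dataclass(frozen=True)
class LatentPrevalence:
    """Ground-truth daily prevalence per area, values in [0, 1]."""

    values: pd.DataFrame  # wide: daily index x areas

    def validate(self) -> "LatentPrevalence":
        v = self.values.to_numpy()
        if np.isnan(v).any():
            raise ValueError("latent prevalence contains NaN")
        if ((v < 0) | (v > 1)).any():
            raise ValueError("latent prevalence outside [0, 1]")
        return self


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _extended_index(config: ScenarioConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(config.start_date) - pd.Timedelta(days=_BUFFER_DAYS)
    return pd.date_range(start, config.index[-1], freq="D")


def generate_drivers(config: ScenarioConfig) -> DriverBundle:
    """Simulate all exogenous driver series for one scenario.

    * Fatalities: a Poisson baseline interrupted by rare conflict
      episodes (geometric duration, elevated rate), giving overdispersed
      daily counts with burst structure.
    * Rainfall: dekadal Gamma draws around a sinusoidal seasonal mean
      curve whose values double as the "historical average" baseline.
    * NDVI: a smoothed, one-dekad-lagged response to seasonal rainfall
      plus noise, clipped to [-1, 1], with a matching deterministic
      baseline.
    * Prices: per-market geometric random walk with occasional upward
      shock jumps; two markets per area.
    * Statics: plausible population/geometry/waterway attributes.
    """
    config.validate()
    (
        rng_conflict,
        rng_rain,
        rng_ndvi,
        rng_price,
        rng_static,
    ) = _streams(config.seed, 5)
    idx = _extended_index(config)
    areas = config.areas
    n_days = len(idx)

    # --- conflict fatalities -------------------------------------------------
    counts = np.zeros((n_days, len(areas)))
    for a in range(len(areas)):
        in_burst = False
        remaining = 0
        for t in range(n_days):
            if not in_burst and config.burst_rate > 0:
                if rng_conflict.random() < config.burst_rate:
                    in_burst = True
                    remaining = 1 + rng_conflict.geometric(
                        1.0 / config.burst_mean_duration
                    )
            rate = config.burst_fatality_rate if in_burst else config.base_fatality_rate
            counts[t, a] = rng_conflict.poisson(rate)
            if in_burst:
                remaining -= 1
                in_burst = remaining > 0
    fatalities_daily = pd.DataFrame(
        counts,
        index=pd.DatetimeIndex(idx, name="date"),
        columns=pd.Index(areas, name="area_id"),
    )
    long = fatalities_daily.stack()
    long = long[long > 0]
    events = long.rename("fatalities").reset_index()[
        ["area_id", "date", "fatalities"]
    ]

    # --- rainfall ------------------------------------------------------------
    doy = np.arange(1, 37)
    dek_idx = features.dekad_index(idx[0], idx[-1])
    base_mm = 25.0
    baseline_cols = {}
    rain_cols = {}
    for a, area in enumerate(areas):
        peak = 18 + (a % 5)  # slight phase shifts between areas
        seasonal = base_mm * np.clip(
            1.0 + 1.0 * np.cos(2 * np.pi * (doy - peak) / 36.0), 0.02, None
        )
        baseline_cols[area] = seasonal
        mean = seasonal[features.dekad_of_year(dek_idx) - 1]
        shape = 2.0
        rain_cols[area] = rng_rain.gamma(shape, mean / shape)
    rainfall_baseline = pd.DataFrame(baseline_cols, index=pd.Index(doy, name="dekad_of_year"))
    rainfall_dekads = pd.DataFrame(rain_cols, index=dek_idx)

    # --- NDVI ----------------------------------------------------------------
    ndvi_cols = {}
    ndvi_base_cols = {}
    for area in areas:
        rain = rainfall_dekads[area].to_numpy()
        seasonal = rainfall_baseline[area].to_numpy()
        smooth = pd.Series(rain).rolling(3, min_periods=1).mean().shift(1).bfill()
        resp = 0.15 + 0.5 * smooth.to_numpy() / (seasonal.max() + 1e-9)
        noise = rng_ndvi.normal(0.0, 0.02, size=resp.size)
        ndvi_cols[area] = np.clip(resp + noise, -1.0, 1.0)
        base_smooth = (
            pd.Series(seasonal).rolling(3, min_periods=1).mean().shift(1).bfill()
        )
        ndvi_base_cols[area] = np.clip(
            0.15 + 0.5 * base_smooth.to_numpy() / (seasonal.max() + 1e-9), -1.0, 1.0
        )
    ndvi_dekads = pd.DataFrame(ndvi_cols, index=dek_idx)
    ndvi_baseline = pd.DataFrame(
        ndvi_base_cols, index=pd.Index(doy, name="dekad_of_year")
    )

    # --- prices --------------------------------------------------------------
    months = pd.period_range(idx[0], idx[-1], freq="M").start_time
    price_rows = []
    for area in areas:
        for market in ("market_a", "market_b"):
            level = rng_price.uniform(80.0, 160.0)
            steps = rng_price.normal(0.004, 0.02, size=len(months))
            shocks = (rng_price.random(len(months)) < 0.05) * rng_price.normal(
                0.12, 0.04, size=len(months)
            )
            series = level * np.exp(np.cumsum(steps + shocks))
            for month, price in zip(months, series):
                price_rows.append((area, market, month, float(price)))
    prices = pd.DataFrame(
        price_rows, columns=["area_id", "market", "month", "price"]
    )

    # --- Ramadan calendar ----------------------------------------------------
    ram_days: list[pd.Timestamp] = []
    for start, end in config.ramadan_intervals:
        ram_days.extend(pd.date_range(pd.Timestamp(start), pd.Timestamp(end)))
    ramadan_calendar = pd.DatetimeIndex(sorted(set(ram_days)))

    # --- static attributes ---------------------------------------------------
    statics = pd.DataFrame(
        {
            "population": rng_static.uniform(2e5, 4e6, len(areas)).round(),
            "total_area": rng_static.uniform(1e3, 5e4, len(areas)).round(1),
            "latitude": rng_static.uniform(12.0, 18.0, len(areas)).round(3),
            "longitude": rng_static.uniform(42.0, 53.0, len(areas)).round(3),
            "waterways": rng_static.uniform(0.0, 500.0, len(areas)).round(1),
        },
        index=pd.Index(areas, name="area_id"),
    )

    return DriverBundle(
        events=events,
        fatalities_daily=fatalities_daily,
        rainfall_dekads=rainfall_dekads,
        rainfall_baseline=rainfall_baseline,
        ndvi_dekads=ndvi_dekads,
        ndvi_baseline=ndvi_baseline,
        prices=prices,
        ramadan_calendar=ramadan_calendar,
        statics=statics,
    ).validate()


def daily_driver_features(
    drivers: DriverBundle, config: ScenarioConfig, index: pd.DatetimeIndex
) -> dict[str, pd.DataFrame | pd.Series]:
    """Daily driver series on ``index`` in the model's own aggregation.

    fatalities: trailing d-day sums; price: normalised monthly average
    forward-filled to days; rainfall/NDVI: raw mm / index plus their
    percent-of-average anomalies; ramadan: trailing-window day counts.
    """
    d = config.rolling_window_d
    intervals = [
        (pd.Timestamp(s), pd.Timestamp(e)) for s, e in config.ramadan_intervals
    ]
    return {
        "fatalities": features.aggregate_fatalities(
            drivers.events, d, index=index
        ),
        "price": features.monthly_price(drivers.prices, index=index),
        "rainfall": features.expand_dekads_daily(
            drivers.rainfall_dekads, index
        ),
        "rainfall_anom_1m": features.rainfall_anomaly(
            drivers.rainfall_dekads, drivers.rainfall_baseline, 3, index=index
        ),
        "rainfall_anom_3m": features.rainfall_anomaly(
            drivers.rainfall_dekads, drivers.rainfall_baseline, 9, index=index
        ),
        "ndvi": features.expand_dekads_daily(drivers.ndvi_dekads, index),
        "ndvi_anom": features.ndvi_anomaly(
            drivers.ndvi_dekads, drivers.ndvi_baseline, index=index
        ),
        "ramadan": features.ramadan_counter(index, intervals, d),
    }


def _zscore(frame: pd.DataFrame) -> pd.DataFrame:
    mean = frame.mean()
    std = frame.std(ddof=0)
    std = std.where(std > 0, 1.0)
    return (frame - mean) / std


def generate_latent_prevalence(
    drivers: DriverBundle, config: ScenarioConfig
) -> LatentPrevalence:
    """Latent daily prevalence from lagged driver effects plus AR(1) noise.

    On the logit scale, prevalence at day t combines the configured
    intercept, each standardised driver evaluated ``driver_lag`` days
    earlier (the Ramadan counter enters contemporaneously — it is a known
    calendar), and a stationary AR(1) disturbance.  The logistic link
    keeps values in (0, 1).
    """
    config.validate()
    ext_idx = _extended_index(config)
    if not ext_idx.isin(drivers.fatalities_daily.index).all():
        raise ValueError("drivers do not cover the configured date range")
    daily = daily_driver_features(drivers, config, ext_idx)
    idx = config.index
    areas = config.areas

    logit = pd.DataFrame(config.intercept, index=idx, columns=areas)
    for name, coef in config.driver_coefficients.items():
        if coef == 0.0:
            continue
        series = daily[name]
        if isinstance(series, pd.Series):
            frame = pd.DataFrame({a: series for a in areas})
        else:
            frame = series[areas]
        frame = frame.ffill().bfill()
        z = _zscore(frame)
        lag = 0 if name == "ramadan" else config.driver_lag
        lagged = z.shift(lag).bfill()
        logit = logit + coef * lagged.loc[idx]

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(6)[5])
    if config.noise_sd > 0:
        rho = config.ar1_rho
        innov = rng.normal(0.0, config.noise_sd, size=(len(idx), len(areas)))
        noise = np.empty_like(innov)
        stationary_sd = config.noise_sd / np.sqrt(1.0 - rho**2)
        noise[0] = rng.normal(0.0, stationary_sd, size=len(areas))
        for t in range(1, len(idx)):
            noise[t] = rho * noise[t - 1] + innov[t]
        logit = logit + noise

    values = 1.0 / (1.0 + np.exp(-logit))
    return LatentPrevalence(values=values).validate()


def _sample_freqs_for_class(
    rng: np.random.Generator,
    insufficient: np.ndarray,
    scheme: FcsScheme,
    max_iter: int = 1000,
) -> np.ndarray:
    """Food-group frequency vectors consistent with each household's class.

    Class is drawn first (Bernoulli on the latent prevalence, done by the
    caller); frequencies are then drawn from class-specific binomial
    proposals and re-drawn until the FCS classification matches, which
    guarantees exact class marginals.
    """
    n = insufficient.size
    k = len(FOOD_COLUMNS)
    freqs = np.zeros((n, k), dtype=np.int64)
    pending = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        if not pending.any():
            break
        ii = np.flatnonzero(pending)
        p = np.where(insufficient[ii], 0.12, 0.55)
        draw = rng.binomial(7, p[:, None], size=(ii.size, k))
        score = np.asarray(compute_fcs(draw.astype(float), scheme))
        ok = (score <= scheme.borderline_threshold) == insufficient[ii]
        freqs[ii[ok]] = draw[ok]
        pending[ii[ok]] = False
    if pending.any():
        raise RuntimeError("rejection sampling failed to match FCS classes")
    return freqs


def sample_household_surveys(
    latent: LatentPrevalence,
    config: ScenarioConfig,
    fcs_scheme: FcsScheme = FcsScheme(),
    rcsi_scheme: RcsiScheme = RcsiScheme(),
) -> pd.DataFrame:
    """Sample daily household interview records from the latent prevalence.

    Per area-day, ``households_per_day`` households are interviewed.  A
    household's insufficient/acceptable class is Bernoulli on the latent
    prevalence of its area-day; food-group frequencies are drawn
    conditional on the class (see :func:`_sample_freqs_for_class`), and
    coping frequencies are higher on average for insufficient households
    (so rCSI-based coping prevalence co-moves with the target).
    Post-stratification weights are i.i.d. lognormal with unit mean —
    the weight law is a modelling choice, not an estimated quantity.
    With ``gap_fraction > 0`` a random subset of area-days yields no
    interviews, exercising gap interpolation downstream.
    """
    config.validate()
    values = latent.values
    if not config.index.isin(values.index).all():
        raise ValueError("latent prevalence does not cover the configured range")
    values = values.loc[config.index, config.areas]
    rng_class, rng_food, rng_cope, rng_weight, rng_gap = _streams(
        config.seed + 1_000_003, 5
    )

    n_days, n_areas = values.shape
    hpd = config.households_per_day
    keep_day = np.ones((n_days, n_areas), dtype=bool)
    if config.gap_fraction > 0:
        keep_day = rng_gap.random((n_days, n_areas)) >= config.gap_fraction

    p = np.repeat(values.to_numpy()[keep_day], hpd)
    n_total = p.size
    day_idx, area_idx = np.nonzero(keep_day)
    dates = np.repeat(values.index.to_numpy()[day_idx], hpd)
    area_ids = np.repeat(np.asarray(config.areas, dtype=object)[area_idx], hpd)

    insufficient = rng_class.random(n_total) < p
    food = _sample_freqs_for_class(rng_food, insufficient, fcs_scheme)
    cope_p = np.where(insufficient, 0.45, 0.12)
    coping = rng_cope.binomial(7, cope_p[:, None], size=(n_total, len(COPING_COLUMNS)))

    sigma = config.weight_sigma
    mu = -0.5 * sigma**2  # unit-mean lognormal
    weight_pop = rng_weight.lognormal(mu, sigma, n_total) if sigma > 0 else np.ones(n_total)
    weight_demo = rng_weight.lognormal(mu, sigma, n_total) if sigma > 0 else np.ones(n_total)
    stratum = np.where(rng_weight.random(n_total) < 0.6, "rural", "urban")

    out = pd.DataFrame(
        {
            "area_id": area_ids,
            "interview_date": dates,
            "stratum": stratum,
            "weight_pop": weight_pop,
            "weight_demo": weight_demo,
        }
    )
    for j, col in enumerate(FOOD_COLUMNS):
        out[col] = food[:, j]
    for j, col in enumerate(COPING_COLUMNS):
        out[col] = coping[:, j]
    return out


def generate_scenario(
    config: ScenarioConfig,
    fcs_scheme: FcsScheme = FcsScheme(),
    rcsi_scheme: RcsiScheme = RcsiScheme(),
) -> tuple[DriverBundle, LatentPrevalence, pd.DataFrame]:
    """Drivers, latent prevalence and surveys for one config, in one call."""
    drivers = generate_drivers(config)
    latent = generate_latent_prevalence(drivers, config)
    surveys = sample_household_surveys(latent, config, fcs_scheme, rcsi_scheme)
    return drivers, latent, surveys
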