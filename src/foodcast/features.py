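"""Predictor construction for the forecasting models.

Exogenous drivers (conflict fatalities, market prices, rainfall, NDVI,
Ramadan) are aggregated to daily area-level series on the same calendar
as the target prevalence, screened for collinearity (pairwise |r| pruning
within a category, then a VIF check), and assembled into lagged design
matrices — one per forecasting horizon — in which every feature is
measurable from information available up to the reference date.

Conventions
-----------
* Area-day series are wide DataFrames: daily DatetimeIndex x area columns.
* Dekads are the standard 10-day reporting periods starting on the 1st,
  11th and 21st of each month (the third dekad absorbs month-end days);
  there are 36 per year.
* Anomalies are percent-of-average: 100 means equal to the historical
  mean for that time of year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LagConfig",
    "dekad_of_year",
    "dekad_start",
    "dekad_index",
    "expand_dekads_daily",
    "aggregate_fatalities",
    "monthly_price",
    "rainfall_anomaly",
    "ndvi_anomaly",
    "ramadan_counter",
    "correlation_prune",
    "vif_screen",
    "build_design",
]

STATIC_COLUMNS = ("population", "total_area", "latitude", "longitude", "waterways")


# ---------------------------------------------------------------------------
# dekad helpers


def dekad_of_year(dates: pd.DatetimeIndex | pd.Timestamp) -> np.ndarray | int:
    """Dekad number within the year, 1..36."""
    idx = pd.DatetimeIndex([dates]) if isinstance(dates, pd.Timestamp) else dates
    within_month = np.minimum((idx.day - 1) // 10, 2)
    doy = (idx.month - 1) * 3 + within_month + 1
    return int(doy[0]) if isinstance(dates, pd.Timestamp) else np.asarray(doy)


def dekad_start(dates: pd.DatetimeIndex | pd.Timestamp) -> pd.DatetimeIndex | pd.Timestamp:
    """First day of the dekad containing each date (1st, 11th or 21st)."""
    scalar = isinstance(dates, pd.Timestamp)
    idx = pd.DatetimeIndex([dates]) if scalar else pd.DatetimeIndex(dates)
    day = np.minimum((idx.day - 1) // 10, 2) * 10 + 1
    out = pd.to_datetime(
        {"year": idx.year, "month": idx.month, "day": day}
    )
    out = pd.DatetimeIndex(out)
    return out[0] if scalar else out


def dekad_index(start: pd.Timestamp, end: pd.Timestamp) -> pd.DatetimeIndex:
    """All dekad start dates covering [start, end]."""
    days = pd.date_range(dekad_start(pd.Timestamp(start)), end, freq="D")
    starts = days[(days.day == 1) | (days.day == 11) | (days.day == 21)]
    return pd.DatetimeIndex(starts)


def expand_dekads_daily(
    dekads: pd.DataFrame, index: pd.DatetimeIndex
) -> pd.DataFrame:
    """Repeat each dekadal value over the days of its dekad."""
    keys = dekad_start(index)
    out = dekads.reindex(keys)
    out.index = index
    return out


# ---------------------------------------------------------------------------
# driver aggregation


def aggregate_fatalities(
    events: pd.DataFrame, d: int, index: pd.DatetimeIndex | None = None
) -> pd.DataFrame:
    """Fatalities summed per area over the trailing d-day window (t-d, t].

    ``events`` is a long frame with columns ``area_id``, ``date``,
    ``fatalities`` (one row per conflict event; days without events
    contribute zero).  The aggregation window matches the one used to
    build the target prevalence, so both indicators describe the same
    d days of history.
    """
    if d < 1:
        raise ValueError("window length d must be >= 1")
    if (events["fatalities"] < 0).any():
        raise ValueError("fatality counts must be nonnegative")
    ev = events.assign(date=pd.to_datetime(events["date"]))
    daily = (
        ev.groupby(["date", "area_id"])["fatalities"].sum().unstack("area_id")
    )
    if index is None:
        index = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    daily = daily.reindex(index).fillna(0.0)
    out = daily.rolling(window=d, min_periods=1).sum()
    out.index.name = "date"
    return out


def monthly_price(
    prices_by_market: pd.DataFrame,
    index: pd.DatetimeIndex | None = None,
    normalization_end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Area-level normalised staple price series.

    Each market's monthly price series is divided by the mean of its own
    history — an expanding mean up to and including the current month by
    default, so the value for month t never depends on later data; pass
    ``normalization_end`` to use a fixed training-period mean instead.
    Normalised series are then averaged across the markets of the area.
    With ``index`` given, the monthly values are forward-filled to daily
    resolution.

    ``prices_by_market`` columns: ``area_id``, ``market``, ``month``
    (any day within the month), ``price`` (> 0, local currency).
    """
    df = prices_by_market.copy()
    if (df["price"] <= 0).any():
        raise ValueError("prices must be positive")
    df["month"] = pd.to_datetime(df["month"]).dt.to_period("M").dt.start_time
    df = df.sort_values(["area_id", "market", "month"], kind="stable")
    if normalization_end is not None:
        norm = df[df["month"] <= pd.Timestamp(normalization_end)]
        means = norm.groupby(["area_id", "market"])["price"].mean()
        keyed = df.set_index(["area_id", "market"])
        df["normalized"] = (
            keyed["price"] / means.reindex(keyed.index)
        ).to_numpy()
    else:
        expanding_mean = df.groupby(["area_id", "market"])["price"].transform(
            lambda s: s.expanding().mean()
        )
        df["normalized"] = df["price"] / expanding_mean
    monthly = (
        df.groupby(["month", "area_id"])["normalized"].mean().unstack("area_id")
    )
    if index is None:
        return monthly
    out = monthly.reindex(
        pd.DatetimeIndex(index.to_period("M").start_time)
    ).ffill()
    out.index = index
    out.index.name = "date"
    return out


def _trailing_anomaly(
    dekads: pd.DataFrame, baseline: pd.DataFrame, span_dekads: int
) -> pd.DataFrame:
    doy = dekad_of_year(pd.DatetimeIndex(dekads.index))
    base = baseline.reindex(doy)
    base.index = dekads.index
    base = base[dekads.columns]
    obs_sum = dekads.rolling(window=span_dekads, min_periods=span_dekads).sum()
    base_sum = base.rolling(window=span_dekads, min_periods=span_dekads).sum()
    zero = (base_sum <= 0) & obs_sum.notna()
    if zero.to_numpy().any():
        warnings.warn(
            "zero historical baseline in anomaly window; values set missing",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        anom = 100.0 * obs_sum / base_sum
    return anom.where(base_sum > 0)


def rainfall_anomaly(
    dekads: pd.DataFrame,
    baseline: pd.DataFrame,
    span_dekads: int = 3,
    index: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Trailing rainfall as percent of the historical average.

    The anomaly at dekad k is 100 x (rainfall summed over the trailing
    ``span_dekads`` dekads) / (historical dekad means summed over the same
    dekads of the year).  ``span_dekads=3`` gives the 1-month anomaly,
    ``9`` the 3-month anomaly.  Dekads whose baseline sum is zero are
    missing.  With ``index`` given, values are repeated to daily
    resolution.

    ``dekads``: wide frame indexed by dekad start dates; ``baseline``:
    wide frame indexed by dekad-of-year 1..36 with the same area columns.
    """
    if span_dekads < 1:
        raise ValueError("span_dekads must be >= 1")
    anom = _trailing_anomaly(dekads, baseline, span_dekads)
    if index is None:
        return anom
    return expand_dekads_daily(anom, index)


def ndvi_anomaly(
    dekads: pd.DataFrame,
    baseline: pd.DataFrame,
    index: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """NDVI as percent of the historical dekad average (single-dekad span).

    Vegetation already integrates past rainfall, so no multi-dekad window
    is applied.
    """
    return rainfall_anomaly(dekads, baseline, span_dekads=1, index=index)


def ramadan_counter(
    index: pd.DatetimeIndex,
    ramadan_intervals: Sequence[tuple[pd.Timestamp, pd.Timestamp]],
    d: int,
) -> pd.Series:
    """Number of Ramadan days inside the trailing d-day window (t-d, t].

    Zero outside Ramadan (and more than d days after it ends); during and
    shortly after Ramadan it ramps between 1 and min(d, Ramadan length),
    tracking how much of the consumption-recall window overlaps the
    observance.
    """
    if d < 1:
        raise ValueError("window length d must be >= 1")
    in_ramadan = pd.Series(0.0, index=index)
    for start, end in ramadan_intervals:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if end < start:
            raise ValueError(f"ill-ordered Ramadan interval ({start}, {end})")
        in_ramadan[(index >= start) & (index <= end)] = 1.0
    out = in_ramadan.rolling(window=d, min_periods=1).sum()
    out.name = "ramadan"
    return out


# ---------------------------------------------------------------------------
# collinearity screening


def correlation_prune(
    series_by_name: pd.DataFrame | Mapping[str, Sequence[float]],
    threshold: float = 0.45,
) -> tuple[list[str], list[str]]:
    """Greedy pairwise-correlation pruning within a variable category.

    Pearson r is computed on pairwise-complete observations.  While any
    surviving pair has |r| > threshold, the pair with the largest |r| is
    examined and the member with the larger mean absolute correlation to
    the other survivors is dropped (ties broken by dropping the later
    name alphabetically).  Constant series yield undefined r, treated as
    0 with a warning.

    Returns (kept, dropped), each in the input's column order.
    """
    df = (
        series_by_name
        if isinstance(series_by_name, pd.DataFrame)
        else pd.DataFrame(dict(series_by_name))
    )
    if df.shape[1] < 2:
        return list(df.columns), []
    corr = df.corr(method="pearson")
    if corr.isna().to_numpy().any():
        warnings.warn(
            "undefined correlations (constant series?) treated as 0",
            stacklevel=2,
        )
        corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 0.0)
    kept = list(df.columns)
    dropped: list[str] = []
    while len(kept) > 1:
        sub = corr.loc[kept, kept].abs()
        max_r = sub.to_numpy().max()
        if max_r <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub.to_numpy()), sub.shape)
        a, b = sub.index[i], sub.columns[j]
        mean_a, mean_b = sub.loc[a].mean(), sub.loc[b].mean()
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:
            victim = max(str(a), str(b))
        kept.remove(victim)
        dropped.append(victim)
    return kept, [c for c in df.columns if c in dropped]


def vif_screen(
    feature_matrix: pd.DataFrame, flag_threshold: float = 3.0
) -> pd.Series:
    """Variance inflation factor of every feature.

    VIF_j = 1 / (1 - R2_j) where R2_j comes from regressing feature j
    (with intercept) on all the others.  Exactly collinear features get
    ``inf``.  A value >= ``flag_threshold`` signals multicollinearity
    worth investigating; the conventional screen here accepts designs
    with all VIFs below 3.
    """
    X = feature_matrix.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least two features")
    if n <= p:
        raise ValueError("need more rows than features")
    if np.isnan(X).any():
        raise ValueError("VIF requires complete rows; drop or impute NaNs")
    out = {}
    for j, name in enumerate(feature_matrix.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float((resid**2).sum())
        if ss_tot == 0.0:
            r2 = 0.0  # constant feature carries no collinearity signal
        else:
            r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# design matrix


@dataclass(frozen=True)
class LagConfig:
    """Backward lags (in days) applied to each feature family.

    Lag 0 means the value on the reference date itself; all lags must be
    nonnegative so every feature is known by the reference date.
    """

    target: tuple[int, ...] = tuple(range(31))
    rcsi: tuple[int, ...] = tuple(range(31))
    drivers: tuple[int, ...] = (0, 7, 14, 30)

    def __post_init__(self) -> None:
        for name in ("target", "rcsi", "drivers"):
            lags = getattr(self, name)
            if any(lag < 0 for lag in lags):
                raise ValueError(
                    f"negative {name} lag would leak future information"
                )
            if len(set(lags)) != len(lags):
                raise ValueError(f"duplicate {name} lags")


def build_design(
    target: pd.DataFrame,
    rcsi: pd.DataFrame | None,
    drivers: Mapping[str, pd.DataFrame | pd.Series],
    statics: pd.DataFrame | None,
    lags: LagConfig = LagConfig(),
    horizons: Iterable[int] = range(1, 31),
) -> dict[int, pd.DataFrame]:
    """Assemble one lagged design matrix per forecasting horizon.

    Each row is keyed by (area, reference date) and pairs features built
    exclusively from information dated on or before the reference date
    with the target prevalence ``h`` days later.  Feature columns:

    * ``target_lag{l}``, ``rcsi_lag{l}`` — lagged endogenous series;
    * ``{driver}_lag{l}`` — lagged exogenous drivers (a driver given as a
      Series is shared across areas, e.g. the Ramadan counter);
    * static area attributes (population, geometry, waterways);
    * ``day``, ``month``, ``year`` — calendar identifiers of the
      *forecast* date (reference date + h).

    Rows whose target is missing are dropped; rows with missing feature
    values are kept (the boosted-tree learner routes missing values
    natively).  Returns ``{h: DataFrame}`` with index (area_id, ref_date)
    and extra columns ``y`` (the target) and ``target_date``.
    """
    horizons = sorted(int(h) for h in horizons)
    if not horizons or horizons[0] < 1:
        raise ValueError("horizons must be positive integers")
    index = target.index
    if not index.is_monotonic_increasing or index.inferred_freq not in ("D", None):
        index = index.sort_values()
    target = target.copy()
    target.columns = [str(c) for c in target.columns]
    areas = list(target.columns)

    aligned: dict[str, pd.DataFrame] = {}
    for name, frame in drivers.items():
        if isinstance(frame, pd.Series):
            frame = pd.DataFrame({a: frame for a in areas})
        missing_areas = [a for a in areas if a not in map(str, frame.columns)]
        if missing_areas:
            raise ValueError(f"driver {name!r} missing areas {missing_areas}")
        frame = frame.copy()
        frame.columns = [str(c) for c in frame.columns]
        aligned[name] = frame.reindex(index)[areas]
    if rcsi is not None:
        r = rcsi.copy()
        r.columns = [str(c) for c in r.columns]
        missing_areas = [a for a in areas if a not in r.columns]
        if missing_areas:
            raise ValueError(f"rCSI series missing areas {missing_areas}")
        rcsi = r.reindex(index)[areas]

    blocks = []
    for area in areas:
        cols: dict[str, np.ndarray] = {}
        t = target[area]
        for lag in lags.target:
            cols[f"target_lag{lag}"] = t.shift(lag).to_numpy()
        if rcsi is not None:
            for lag in lags.rcsi:
                cols[f"rcsi_lag{lag}"] = rcsi[area].shift(lag).to_numpy()
        for name, frame in aligned.items():
            for lag in lags.drivers:
                cols[f"{name}_lag{lag}"] = frame[area].shift(lag).to_numpy()
        block = pd.DataFrame(cols, index=index)
        if statics is not None:
            if str(area) not in map(str, statics.index):
                raise ValueError(f"statics missing area {area!r}")
            srow = statics.loc[statics.index.astype(str) == str(area)].iloc[0]
            for col in statics.columns:
                block[col] = float(srow[col])
        block["area_id"] = area
        blocks.append(block)

    feature_frame = pd.concat(blocks)
    feature_frame.index.name = "ref_date"

    designs: dict[int, pd.DataFrame] = {}
    target_long = {a: target[a] for a in areas}
    for h in horizons:
        parts = []
        offset = pd.Timedelta(days=h)
        for area, block in zip(areas, blocks):
            y = target_long[area].shift(-h)
            df = block.copy()
            df["y"] = y.to_numpy()
            df["target_date"] = df.index + offset
            df = df[df["y"].notna()]
            parts.append(df)
        dh = pd.concat(parts)
        dh.index.name = "ref_date"
        forecast_dates = pd.DatetimeIndex(dh["target_date"])
        dh["day"] = forecast_dates.day.astype(float)
        dh["month"] = forecast_dates.month.astype(float)
        dh["year"] = forecast_dates.year.astype(float)
        dh = dh.set_index("area_id", append=True).reorder_levels(
            ["area_id", "ref_date"]
        )
        designs[h] = dh
    return designs


def feature_columns(design: pd.DataFrame) -> list[str]:
    """Model input columns of a design frame (everything but y/target_date)."""
    return [c for c in design.columns if c not in ("y", "target_date")]
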