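"""CSV schemas and round-trip readers/writers for every pipeline artifact.

All files are long-format UTF-8 CSV with ISO-8601 dates, string area
identifiers and empty fields for missing values, so each stage's output
can be inspected with any spreadsheet or command-line tool.  Readers
validate types and report the offending row number on failure.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .indicators import COPING_COLUMNS, FOOD_COLUMNS

__all__ = [
    "SchemaError",
    "read_surveys",
    "write_surveys",
    "read_area_day",
    "write_area_day",
    "wide_to_long",
    "long_to_wide",
    "read_events",
    "write_events",
    "read_dekads",
    "write_dekads",
    "read_baseline",
    "write_baseline",
    "read_prices",
    "write_prices",
    "read_statics",
    "write_statics",
]

SURVEY_COLUMNS = (
    "area_id",
    "interview_date",
    "stratum",
    "weight_pop",
    "weight_demo",
    *FOOD_COLUMNS,
    *COPING_COLUMNS,
)


class SchemaError(ValueError):
    """A CSV file violates its expected schema."""


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _parse_dates(df: pd.DataFrame, col: str, path) -> pd.DataFrame:
    parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: malformed date {df[col].iloc[row]!r} in column "
            f"{col!r} at data row {row}"
        )
    out = df.copy()
    out[col] = parsed
    return out


# --- surveys ----------------------------------------------------------------


def write_surveys(surveys: pd.DataFrame, path: str | Path) -> None:
    out = surveys.loc[:, list(SURVEY_COLUMNS)].copy()
    out["interview_date"] = pd.to_datetime(out["interview_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    out.to_csv(path, index=False)


def read_surveys(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str, "stratum": str})
    _require_columns(df, SURVEY_COLUMNS, path)
    df = _parse_dates(df, "interview_date", path)
    for col in (*FOOD_COLUMNS, *COPING_COLUMNS):
        vals = df[col]
        if vals.isna().any() or ((vals < 0) | (vals > 7)).any():
            row = int(
                np.flatnonzero((vals.isna() | (vals < 0) | (vals > 7)).to_numpy())[0]
            )
            raise SchemaError(
                f"{path}: frequency {col!r} out of [0, 7] at data row {row}"
            )
    for col in ("weight_pop", "weight_demo"):
        if (df[col] <= 0).any() or df[col].isna().any():
            row = int(np.flatnonzero((~(df[col] > 0)).to_numpy())[0])
            raise SchemaError(f"{path}: nonpositive {col!r} at data row {row}")
    return df


# --- area-day series --------------------------------------------------------


def wide_to_long(wide: pd.DataFrame, value_name: str = "value") -> pd.DataFrame:
    """(date x area) frame -> long (area_id, date, value) with NaN rows kept."""
    long = wide.copy()
    long.index.name = "date"
    long.columns.name = "area_id"
    out = long.stack(future_stack=True).rename(value_name).reset_index()
    return out[["area_id", "date", value_name]].sort_values(
        ["area_id", "date"], kind="stable", ignore_index=True
    )


def long_to_wide(long: pd.DataFrame, value_name: str = "value") -> pd.DataFrame:
    wide = long.pivot(index="date", columns="area_id", values=value_name)
    wide.index = pd.DatetimeIndex(wide.index)
    return wide.sort_index()


def write_area_day(series: pd.DataFrame, path: str | Path) -> None:
    """Write a wide area-day frame as long CSV (area_id, date, value)."""
    out = wide_to_long(series)
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_area_day(path: str | Path) -> pd.DataFrame:
    """Read a long (area_id, date, value) CSV into a wide daily frame."""
    df = pd.read_csv(path, dtype={"area_id": str})
    _require_columns(df, ("area_id", "date", "value"), path)
    df = _parse_dates(df, "date", path)
    if df.empty:
        return pd.DataFrame(index=pd.DatetimeIndex([], name="date"))
    return long_to_wide(df)


# --- conflict events --------------------------------------------------------


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.loc[:, ["area_id", "date", "fatalities"]].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str})
    _require_columns(df, ("area_id", "date", "fatalities"), path)
    df = _parse_dates(df, "date", path)
    if (df["fatalities"] < 0).any():
        row = int(np.flatnonzero((df["fatalities"] < 0).to_numpy())[0])
        raise SchemaError(f"{path}: negative fatalities at data row {row}")
    return df


# --- dekadal series and baselines ------------------------------------------


def write_dekads(dekads: pd.DataFrame, path: str | Path) -> None:
    out = wide_to_long(dekads).rename(columns={"date": "dekad_start"})
    out["dekad_start"] = pd.to_datetime(out["dekad_start"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_dekads(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str})
    _require_columns(df, ("area_id", "dekad_start", "value"), path)
    df = _parse_dates(df, "dekad_start", path)
    wide = df.pivot(index="dekad_start", columns="area_id", values="value")
    wide.index = pd.DatetimeIndex(wide.index)
    return wide.sort_index()


def write_baseline(baseline: pd.DataFrame, path: str | Path) -> None:
    long = baseline.copy()
    long.index.name = "dekad_of_year"
    long.columns.name = "area_id"
    out = long.stack(future_stack=True).rename("value").reset_index()
    out[["area_id", "dekad_of_year", "value"]].to_csv(path, index=False)


def read_baseline(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str})
    _require_columns(df, ("area_id", "dekad_of_year", "value"), path)
    wide = df.pivot(index="dekad_of_year", columns="area_id", values="value")
    return wide.sort_index()


# --- prices and statics -----------------------------------------------------


def write_prices(prices: pd.DataFrame, path: str | Path) -> None:
    out = prices.loc[:, ["area_id", "market", "month", "price"]].copy()
    out["month"] = pd.to_datetime(out["month"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_prices(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str, "market": str})
    _require_columns(df, ("area_id", "market", "month", "price"), path)
    df = _parse_dates(df, "month", path)
    if (df["price"] <= 0).any():
        row = int(np.flatnonzero((~(df["price"] > 0)).to_numpy())[0])
        raise SchemaError(f"{path}: nonpositive price at data row {row}")
    return df


def write_statics(statics: pd.DataFrame, path: str | Path) -> None:
    statics.rename_axis("area_id").to_csv(path)


def read_statics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"area_id": str})
    _require_columns(
        df,
        ("area_id", "population", "total_area", "latitude", "longitude", "waterways"),
        path,
    )
    return df.set_index("area_id")
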