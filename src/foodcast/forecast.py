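"""Multi-horizon gradient-boosted forecasting with a persistence baseline.

Thirty separate boosted-tree regressors — one per forecasting horizon
h = 1..30 days — each predict the area-level prevalence h days after a
reference date from lagged endogenous and exogenous features known by
that date.  Evaluation uses time-ordered monthly splits: each split
holds out one calendar month at the tail of the series, forecasts are
launched from the day before the month starts, and everything at or
after the month start is invisible to training and prediction.

Hyper-parameters (and, optionally, the lag-set preset) are selected on a
time-ordered 80/20 train/validation split of each split's training
region; the winning configuration is refit on the full region before
testing.  The benchmark is the naive persistence forecast: the last
observed value before the test month, at every horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from xgboost import XGBRegressor

from .features import LagConfig, build_design, feature_columns

__all__ = [
    "Split",
    "DEFAULT_GRID",
    "REDUCED_GRID",
    "make_splits",
    "naive_forecast",
    "HorizonModelSet",
    "fit_horizon_models",
    "predict_paths",
    "forecast_experiment",
]

#: Default hyper-parameter grid.  n_estimators is a cap; the effective
#: number of rounds is chosen by early stopping on the validation block.
DEFAULT_GRID: tuple[dict[str, Any], ...] = tuple(
    {"max_depth": d, "learning_rate": lr, "subsample": s}
    for d in (3, 5, 7)
    for lr in (0.05, 0.1)
    for s in (0.8, 1.0)
)

#: Single-candidate grid for scaled-down experiments.
REDUCED_GRID: tuple[dict[str, Any], ...] = (
    {"max_depth": 4, "learning_rate": 0.1, "subsample": 1.0},
)

_FIXED_PARAMS = {
    "objective": "reg:squarederror",
    "tree_method": "hist",
    "n_jobs": 1,
    "n_estimators": 400,
    "verbosity": 0,
}
_EARLY_STOPPING_ROUNDS = 20


@dataclass(frozen=True)
class Split:
    """One time-ordered evaluation split.

    ``ref_date`` is the forecast launch day: the last day before the
    held-out test month.  Training may only use rows whose *target* date
    is on or before ``ref_date``.
    """

    split_id: int
    test_start: pd.Timestamp
    test_end: pd.Timestamp

    @property
    def ref_date(self) -> pd.Timestamp:
        return self.test_start - pd.Timedelta(days=1)


def make_splits(index: pd.DatetimeIndex, k: int = 5) -> list[Split]:
    """k monthly test blocks taken from the tail of the calendar.

    The last k *complete* calendar months covered by ``index`` become
    test months, in chronological order (a partial final month cannot
    host a full forecast path and is excluded).  Requires at least k + 2
    covered months so every split retains a training region.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    months = pd.PeriodIndex(index, freq="M").unique().sort_values()
    months = months[
        [m.end_time.normalize() <= index.max() for m in months]
    ]
    if len(months) < k + 2:
        raise ValueError(
            f"series covers {len(months)} complete months; need at least "
            f"{k + 2} for k={k} monthly splits"
        )
    splits = []
    for i, month in enumerate(months[-k:]):
        start = month.start_time.normalize()
        end = min(month.end_time.normalize(), index.max())
        splits.append(Split(split_id=i, test_start=start, test_end=end))
    return splits


def naive_forecast(
    series: pd.Series | pd.DataFrame,
    reference_date: pd.Timestamp,
    horizon: int | None = None,
) -> float | pd.Series:
    """Persistence baseline: the last observed value at or before the
    reference date, for every horizon.

    ``horizon`` is accepted (and ignored) to mirror the model interface.
    """
    reference_date = pd.Timestamp(reference_date)
    past = series.loc[:reference_date]
    if isinstance(series, pd.DataFrame):
        out = past.ffill().iloc[-1] if len(past) else pd.Series(dtype=float)
        if out.isna().any() or out.empty:
            missing = list(out.index[out.isna()]) if not out.empty else "all"
            raise ValueError(f"no prior observation for areas {missing}")
        return out
    past = past.dropna()
    if past.empty:
        raise ValueError(f"no observation at or before {reference_date.date()}")
    return float(past.iloc[-1])


@dataclass
class HorizonModelSet:
    """Fitted per-horizon models plus the configuration that won validation."""

    models: dict[int, XGBRegressor]
    selected: dict[int, dict[str, Any]]
    feature_cols: dict[int, list[str]]
    split: Split
    seed: int

    @property
    def horizons(self) -> list[int]:
        return sorted(self.models)


def _train_rows(design: pd.DataFrame, split: Split) -> pd.DataFrame:
    rows = design[design["target_date"] <= split.ref_date]
    return rows.sort_index(level="ref_date", sort_remaining=True)


def _fit_one(
    X: np.ndarray,
    y: np.ndarray,
    Xv: np.ndarray,
    yv: np.ndarray,
    params: Mapping[str, Any],
    seed: int,
) -> tuple[XGBRegressor, float, int]:
    model = XGBRegressor(
        **_FIXED_PARAMS,
        **params,
        random_state=seed,
        early_stopping_rounds=_EARLY_STOPPING_ROUNDS,
        eval_metric="rmse",
    )
    model.fit(X, y, eval_set=[(Xv, yv)], verbose=False)
    pred = model.predict(Xv)
    mse = float(np.mean((pred - yv) ** 2))
    best_round = int(getattr(model, "best_iteration", model.n_estimators - 1)) + 1
    return model, mse, best_round


def fit_horizon_models(
    designs: Mapping[int, pd.DataFrame],
    split: Split,
    hyper_grid: Sequence[Mapping[str, Any]] = REDUCED_GRID,
    seed: int = 0,
    refit: bool = True,
) -> HorizonModelSet:
    """Select and fit one boosted-tree regressor per horizon.

    For each horizon, every grid candidate is trained on the first 80%
    (by reference date) of the split's training region and scored by MSE
    on the remaining 20%; the best candidate is then refit on the full
    region with the validated number of boosting rounds (``refit=False``
    keeps the 80%-fit model instead).  Deterministic given the seed.
    """
    if not hyper_grid:
        raise ValueError("hyper_grid is empty")
    models: dict[int, XGBRegressor] = {}
    selected: dict[int, dict[str, Any]] = {}
    feat_cols: dict[int, list[str]] = {}
    for h, design in designs.items():
        train = _train_rows(design, split)
        if len(train) < 10:
            raise ValueError(
                f"horizon {h}: only {len(train)} training rows before "
                f"{split.test_start.date()}"
            )
        cols = feature_columns(design)
        X = train[cols].to_numpy(dtype=float)
        y = train["y"].to_numpy(dtype=float)
        n_fit = max(1, int(np.ceil(0.8 * len(train))))
        Xf, yf = X[:n_fit], y[:n_fit]
        Xv, yv = X[n_fit:], y[n_fit:]
        if len(yv) == 0:  # degenerate tiny split: validate on the fit block
            Xv, yv = Xf, yf
        best: tuple[float, int, XGBRegressor, dict[str, Any], int] | None = None
        for gi, params in enumerate(hyper_grid):
            model, mse, best_round = _fit_one(Xf, yf, Xv, yv, params, seed)
            if best is None or mse < best[0]:
                best = (mse, gi, model, dict(params), best_round)
        assert best is not None
        _, _, model, params, best_round = best
        if refit:
            final_params = dict(_FIXED_PARAMS, **params)
            final_params["n_estimators"] = best_round
            model = XGBRegressor(**final_params, random_state=seed)
            model.fit(X, y, verbose=False)
        models[h] = model
        selected[h] = dict(params, n_rounds=best_round)
        feat_cols[h] = cols
    return HorizonModelSet(
        models=models,
        selected=selected,
        feature_cols=feat_cols,
        split=split,
        seed=seed,
    )


def predict_paths(
    model_set: HorizonModelSet, designs: Mapping[int, pd.DataFrame]
) -> pd.DataFrame:
    """Predict every supplied design row with its horizon's model.

    Predictions are clipped to [0, 1] (the target is a prevalence).
    Returns a long frame: area_id, ref_date, target_date, horizon,
    y_true, y_model.
    """
    parts = []
    for h, rows in designs.items():
        if h not in model_set.models:
            raise ValueError(f"no fitted model for horizon {h}")
        cols = model_set.feature_cols[h]
        missing = [c for c in cols if c not in rows.columns]
        if missing:
            raise ValueError(f"design rows missing feature columns {missing}")
        X = rows[cols].to_numpy(dtype=float)
        pred = np.clip(model_set.models[h].predict(X), 0.0, 1.0)
        out = rows.reset_index()[["area_id", "ref_date", "target_date", "y"]].copy()
        out["horizon"] = h
        out["y_model"] = pred
        parts.append(out)
    result = pd.concat(parts, ignore_index=True)
    return result.rename(columns={"y": "y_true"})


def forecast_experiment(
    target: pd.DataFrame,
    rcsi: pd.DataFrame | None,
    drivers: Mapping[str, pd.DataFrame | pd.Series],
    statics: pd.DataFrame | None,
    lags: LagConfig = LagConfig(),
    horizons: Iterable[int] = range(1, 31),
    k: int = 5,
    hyper_grid: Sequence[Mapping[str, Any]] = REDUCED_GRID,
    seed: int = 0,
    test_areas: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the full split/fit/predict cycle and return test predictions.

    For each of the k monthly splits, per-horizon models are selected and
    fit on data whose target dates precede the test month, then evaluated
    on the forecast paths launched from the day before the month: the
    horizon-h test rows are the areas' prevalence h days into the month.
    Naive persistence predictions are attached for benchmarking.

    ``test_areas`` restricts scoring to a subset of areas while training
    on all of them — used by controlled training-size experiments that
    need a common test population across dataset variants.

    Returns a long frame with columns split_id, area_id, ref_date,
    target_date, horizon, y_true, y_model, y_naive.
    """
    horizons = sorted(int(h) for h in horizons)
    designs = build_design(target, rcsi, drivers, statics, lags, horizons)
    splits = make_splits(target.index, k)
    if test_areas is not None:
        test_areas = [str(a) for a in test_areas]
        unknown = set(test_areas) - set(map(str, target.columns))
        if unknown:
            raise ValueError(f"test_areas not in target: {sorted(unknown)}")
    results = []
    for split in splits:
        model_set = fit_horizon_models(designs, split, hyper_grid, seed)
        test_rows = {
            h: d.loc[
                d.index.get_level_values("ref_date") == split.ref_date
            ]
            for h, d in designs.items()
        }
        if test_areas is not None:
            test_rows = {
                h: rows.loc[
                    rows.index.get_level_values("area_id").isin(test_areas)
                ]
                for h, rows in test_rows.items()
            }
        test_rows = {h: rows for h, rows in test_rows.items() if len(rows)}
        if not test_rows:
            continue
        preds = predict_paths(model_set, test_rows)
        naive = naive_forecast(target, split.ref_date)
        preds["y_naive"] = (
            preds["area_id"].map(lambda a: float(naive[a])).to_numpy()
        )
        preds.insert(0, "split_id", split.split_id)
        results.append(preds)
    if not results:
        raise ValueError("no test rows in any split")
    return pd.concat(results, ignore_index=True)
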