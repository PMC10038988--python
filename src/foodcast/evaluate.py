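"""Forecast scoring: per-split R²/MSE, model-vs-naive deltas, learning curves.

R² is the coefficient of determination computed per split and horizon,
pooling all areas of the split (1 - SS_res / SS_tot with the test-set
mean as reference); MSE is the plain mean squared error.  The model's
edge over persistence is summarised as ΔMSE = MSE_naive − MSE_model
(positive when the model wins) and ΔR² = R²_model − R²_naive.

Learning curves re-run the whole forecasting experiment on nested
subsets of the data — truncated in time at a fixed set of areas, or
restricted in areas at a fixed length — and report the mean ± sd of
ΔMSE across splits at weekly horizons, as a function of the number of
training points.
"""

from __future__ import annotations

import warnings
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import LagConfig
from .forecast import REDUCED_GRID, forecast_experiment

__all__ = [
    "score_split",
    "delta_metrics",
    "subset_by_length",
    "subset_by_areas",
    "learning_curve",
]


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(((y - yhat) ** 2).sum()) / ss_tot


def score_split(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-(split, horizon) R² and MSE for the model and the naive baseline.

    ``predictions`` is the long frame from
    :func:`foodcast.forecast.forecast_experiment` (columns ``split_id``,
    ``horizon``, ``y_true``, ``y_model``, ``y_naive``); all areas within a
    split are pooled.  Splits with zero test variance at some horizon get
    R² = NaN with a warning (MSE is still reported).
    """
    rows = []
    warned = False
    for (split_id, horizon), grp in predictions.groupby(["split_id", "horizon"]):
        y = grp["y_true"].to_numpy(dtype=float)
        ym = grp["y_model"].to_numpy(dtype=float)
        yn = grp["y_naive"].to_numpy(dtype=float)
        r2m, r2n = _r2(y, ym), _r2(y, yn)
        if (np.isnan(r2m) or np.isnan(r2n)) and not warned:
            warnings.warn(
                "zero test variance in at least one split; R2 undefined there",
                stacklevel=2,
            )
            warned = True
        rows.append(
            {
                "split_id": split_id,
                "horizon": horizon,
                "r2_model": r2m,
                "r2_naive": r2n,
                "mse_model": float(((y - ym) ** 2).mean()),
                "mse_naive": float(((y - yn) ** 2).mean()),
                "n_test": int(len(grp)),
            }
        )
    return pd.DataFrame.from_records(rows)


def delta_metrics(evaluations: pd.DataFrame) -> pd.DataFrame:
    """Attach ΔR² = R²_model − R²_naive and ΔMSE = MSE_naive − MSE_model.

    Positive ΔMSE means the model outperforms persistence.
    """
    out = evaluations.copy()
    out["delta_r2"] = out["r2_model"] - out["r2_naive"]
    out["delta_mse"] = out["mse_naive"] - out["mse_model"]
    return out


def subset_by_length(
    dataset: Mapping[str, Any], n_days: int
) -> dict[str, Any]:
    """Keep only the last ``n_days`` of the target/rCSI/driver calendars.

    ``dataset`` maps ``target``/``rcsi``/``drivers``/``statics`` to the
    forecasting inputs; areas are untouched, so nested length subsets
    isolate the time-span dimension of training size.
    """
    target = dataset["target"]
    if n_days > len(target.index):
        raise ValueError(f"n_days={n_days} exceeds series length {len(target.index)}")
    idx = target.index[-n_days:]

    def cut(frame):
        if frame is None:
            return None
        return frame.loc[frame.index.intersection(idx)]

    drivers = {
        name: cut(frame) for name, frame in dataset["drivers"].items()
    }
    return {
        "target": target.loc[idx],
        "rcsi": cut(dataset.get("rcsi")),
        "drivers": drivers,
        "statics": dataset.get("statics"),
    }


def subset_by_areas(
    dataset: Mapping[str, Any], n_areas: int
) -> dict[str, Any]:
    """Keep only the first ``n_areas`` area columns at full length."""
    target = dataset["target"]
    if n_areas > target.shape[1]:
        raise ValueError(f"n_areas={n_areas} exceeds {target.shape[1]} areas")
    areas = list(target.columns[:n_areas])

    def cut(frame):
        if frame is None or isinstance(frame, pd.Series):
            return frame
        keep = [c for c in frame.columns if c in areas]
        return frame[keep] if keep else frame
    drivers = {
        name: cut(frame) for name, frame in dataset["drivers"].items()
    }
    statics = dataset.get("statics")
    if statics is not None:
        statics = statics.loc[statics.index.isin(areas)]
    return {
        "target": target[areas],
        "rcsi": cut(dataset.get("rcsi")),
        "drivers": drivers,
        "statics": statics,
    }


def learning_curve(
    variants: Sequence[Mapping[str, Any]],
    lags: LagConfig = LagConfig(),
    horizons: Iterable[int] = (7, 14, 21, 28),
    k: int = 2,
    hyper_grid: Sequence[Mapping[str, Any]] = REDUCED_GRID,
    seed: int = 0,
) -> pd.DataFrame:
    """ΔMSE versus training-set size across dataset variants.

    Each variant is a dict with keys ``label`` (e.g. "fixed-areas" or
    "fixed-length"), ``target``, ``rcsi``, ``drivers``, ``statics`` and
    optionally ``test_areas``.  The full experiment (splits, model
    selection, refit, test) is re-run per variant; the number of training
    points is the product of areas and usable pre-test days, the quantity
    the analysis varies.  Supplying a common ``test_areas`` subset across
    area-count variants keeps the test population fixed, so the curve
    isolates training-set size rather than test-set composition.

    Returns one row per (variant, horizon): columns ``label``,
    ``n_training_points``, ``horizon``, ``horizon_week``,
    ``delta_mse_mean``, ``delta_mse_sd``, ``n_splits``.  Variants too
    small to form k monthly splits are skipped with a warning.
    """
    if len(variants) < 2:
        raise ValueError("need at least two dataset variants")
    horizons = sorted(int(h) for h in horizons)
    rows = []
    for variant in variants:
        target = variant["target"]
        try:
            preds = forecast_experiment(
                target,
                variant.get("rcsi"),
                variant["drivers"],
                variant.get("statics"),
                lags=lags,
                horizons=horizons,
                k=k,
                hyper_grid=hyper_grid,
                seed=seed,
                test_areas=variant.get("test_areas"),
            )
        except ValueError as exc:
            warnings.warn(
                f"variant {variant.get('label')!r} skipped: {exc}", stacklevel=2
            )
            continue
        scored = delta_metrics(score_split(preds))
        # training points: rows with target date before the earliest test month
        splits_start = preds["target_date"].min().to_period("M").start_time
        usable = target.loc[: splits_start - pd.Timedelta(days=1)]
        n_points = int(usable.notna().sum().sum())
        for h, grp in scored.groupby("horizon"):
            rows.append(
                {
                    "label": variant.get("label", ""),
                    "n_training_points": n_points,
                    "horizon": int(h),
                    "horizon_week": int(np.ceil(h / 7)),
                    "delta_mse_mean": float(grp["delta_mse"].mean()),
                    "delta_mse_sd": float(grp["delta_mse"].std(ddof=0)),
                    "n_splits": int(grp["split_id"].nunique()),
                }
            )
    return pd.DataFrame.from_records(rows)
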