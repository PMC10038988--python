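"""Household food-security indicators and area-level prevalence series.

Two standard WFP survey indicators are computed per household:

* **FCS** (Food Consumption Score): a weighted sum of 7-day consumption
  frequencies over eight food groups, with thresholds classifying each
  household as *poor*, *borderline* or *acceptable*.  "Insufficient food
  consumption" means poor-or-borderline.
* **rCSI** (reduced Coping Strategy Index): a severity-weighted sum of
  five food-based coping-behaviour frequencies; a score of 19 or more
  marks crisis-or-above coping.

Daily area-level prevalence is the post-stratification-weighted share of
flagged households interviewed during the previous ``d`` days (a rolling
window), with interior gaps filled by linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FOOD_GROUPS",
    "COPING_STRATEGIES",
    "FcsScheme",
    "RcsiScheme",
    "compute_fcs",
    "classify_fcs",
    "compute_rcsi",
    "fcs_insufficient",
    "rcsi_crisis",
    "rolling_prevalence",
    "interpolate_gaps",
]

#: Food groups in FCS column order.
FOOD_GROUPS = (
    "staples",
    "pulses",
    "vegetables",
    "fruit",
    "meat_fish",
    "milk",
    "sugar",
    "oil",
)

#: Coping strategies in rCSI column order.
COPING_STRATEGIES = (
    "less_preferred",
    "borrow_food",
    "limit_portion",
    "restrict_adults",
    "reduce_meals",
)

FOOD_COLUMNS = tuple(f"fg_{g}" for g in FOOD_GROUPS)
COPING_COLUMNS = tuple(f"cs_{s}" for s in COPING_STRATEGIES)

MAX_FREQUENCY = 7  # frequencies refer to the previous 7 days


@dataclass(frozen=True)
class FcsScheme:
    """FCS nutritional weights and classification thresholds.

    Defaults follow standard WFP practice: group weights
    (2, 3, 1, 1, 4, 4, 0.5, 0.5) for staples, pulses, vegetables, fruit,
    meat/fish, milk, sugar, oil; thresholds 21 (poor) and 35 (borderline),
    with inclusive upper bounds.  Country programmes sometimes raise the
    thresholds to 28/42; both are configurable.
    """

    group_weights: tuple[float, ...] = (2.0, 3.0, 1.0, 1.0, 4.0, 4.0, 0.5, 0.5)
    poor_threshold: float = 21.0
    borderline_threshold: float = 35.0

    def __post_init__(self) -> None:
        if len(self.group_weights) != len(FOOD_GROUPS):
            raise ValueError(
                f"group_weights must have {len(FOOD_GROUPS)} entries, "
                f"got {len(self.group_weights)}"
            )
        if any(w <= 0 for w in self.group_weights):
            raise ValueError("group_weights must be positive")
        if not self.poor_threshold < self.borderline_threshold:
            raise ValueError("poor_threshold must be below borderline_threshold")


@dataclass(frozen=True)
class RcsiScheme:
    """rCSI severity weights and the crisis threshold (inclusive).

    Default weights (1, 2, 1, 3, 1) are the standard severity weights for
    less-preferred food, borrowing, limiting portions, restricting adult
    intake and reducing meal counts; scores >= 19 flag crisis-or-above
    coping.
    """

    strategy_weights: tuple[float, ...] = (1.0, 2.0, 1.0, 3.0, 1.0)
    crisis_threshold: float = 19.0

    def __post_init__(self) -> None:
        if len(self.strategy_weights) != len(COPING_STRATEGIES):
            raise ValueError(
                f"strategy_weights must have {len(COPING_STRATEGIES)} entries"
            )
        if any(w <= 0 for w in self.strategy_weights):
            raise ValueError("strategy_weights must be positive")
        if self.crisis_threshold <= 0:
            raise ValueError("crisis_threshold must be positive")


def _validate_frequencies(freqs: np.ndarray, n_items: int, what: str) -> np.ndarray:
    arr = np.asarray(freqs, dtype=float)
    if arr.shape[-1] != n_items:
        raise ValueError(f"{what} must have {n_items} entries, got {arr.shape[-1]}")
    if np.isnan(arr).any():
        raise ValueError(f"{what} contain missing values")
    if ((arr < 0) | (arr > MAX_FREQUENCY)).any():
        raise ValueError(f"{what} must lie in [0, {MAX_FREQUENCY}]")
    return arr


def compute_fcs(
    food_freqs: Sequence[float] | np.ndarray, scheme: FcsScheme = FcsScheme()
) -> np.ndarray | float:
    """Weighted sum of food-group frequencies.

    ``food_freqs`` may be a single 8-vector or an array of shape (..., 8);
    frequencies must lie in [0, 7].
    """
    arr = _validate_frequencies(food_freqs, len(FOOD_GROUPS), "food frequencies")
    score = arr @ np.asarray(scheme.group_weights)
    return float(score) if score.ndim == 0 else score


def classify_fcs(
    score: float | np.ndarray, scheme: FcsScheme = FcsScheme()
) -> np.ndarray | str:
    """Classify FCS scores as 'poor', 'borderline' or 'acceptable'.

    Boundary convention: poor iff score <= poor_threshold; borderline iff
    poor_threshold < score <= borderline_threshold; else acceptable.
    """
    arr = np.asarray(score, dtype=float)
    if (arr < 0).any():
        raise ValueError("FCS scores must be nonnegative")
    labels = np.where(
        arr <= scheme.poor_threshold,
        "poor",
        np.where(arr <= scheme.borderline_threshold, "borderline", "acceptable"),
    )
    return str(labels) if labels.ndim == 0 else labels


def compute_rcsi(
    coping_freqs: Sequence[float] | np.ndarray, scheme: RcsiScheme = RcsiScheme()
) -> tuple[np.ndarray | float, np.ndarray | bool]:
    """Severity-weighted coping score and crisis flag (score >= threshold)."""
    arr = _validate_frequencies(coping_freqs, len(COPING_STRATEGIES), "coping frequencies")
    score = arr @ np.asarray(scheme.strategy_weights)
    crisis = score >= scheme.crisis_threshold
    if score.ndim == 0:
        return float(score), bool(crisis)
    return score, crisis


def fcs_insufficient(
    scheme: FcsScheme = FcsScheme(),
) -> Callable[[pd.DataFrame], np.ndarray]:
    """Classifier flagging households with poor-or-borderline FCS."""

    def classify(records: pd.DataFrame) -> np.ndarray:
        freqs = records.loc[:, list(FOOD_COLUMNS)].to_numpy(dtype=float)
        score = compute_fcs(freqs, scheme)
        return np.asarray(score) <= scheme.borderline_threshold

    return classify


def rcsi_crisis(
    scheme: RcsiScheme = RcsiScheme(),
) -> Callable[[pd.DataFrame], np.ndarray]:
    """Classifier flagging households with crisis-or-above coping (rCSI >= 19)."""

    def classify(records: pd.DataFrame) -> np.ndarray:
        freqs = records.loc[:, list(COPING_COLUMNS)].to_numpy(dtype=float)
        score, crisis = compute_rcsi(freqs, scheme)
        return np.asarray(crisis)

    return classify


def rolling_prevalence(
    records: pd.DataFrame,
    d: int,
    classifier: Callable[[pd.DataFrame], np.ndarray],
    index: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """Daily weighted prevalence of flagged households per area.

    For each area and day ``t`` the prevalence is the final-weight share of
    flagged households among those interviewed during the half-open window
    ``(t - d, t]`` — i.e. the previous ``d`` days, counting day ``t`` itself.
    The final weight is the product of the population and demographic
    post-stratification weights.  Days whose window contains no interview
    are missing (NaN); fill them afterwards with :func:`interpolate_gaps`.

    Parameters
    ----------
    records
        Survey records with columns ``area_id``, ``interview_date``,
        ``weight_pop``, ``weight_demo`` and the indicator columns the
        classifier needs.
    d
        Rolling-window length in days (>= 1).
    classifier
        Maps the record frame to a boolean "flagged" array, e.g.
        :func:`fcs_insufficient` or :func:`rcsi_crisis`.
    index
        Optional daily calendar to report on; defaults to the span of the
        observed interview dates.

    Returns
    -------
    Wide DataFrame: daily DatetimeIndex x area columns, values in [0, 1].
    """
    if d < 1:
        raise ValueError("window length d must be >= 1")
    if records.empty:
        return pd.DataFrame(index=index if index is not None else pd.DatetimeIndex([]))
    weights = (
        records["weight_pop"].to_numpy(dtype=float)
        * records["weight_demo"].to_numpy(dtype=float)
    )
    if (weights <= 0).any():
        raise ValueError("post-stratification weights must be positive")
    flagged = np.asarray(classifier(records), dtype=float)
    tmp = pd.DataFrame(
        {
            "area_id": records["area_id"].to_numpy(),
            "date": pd.to_datetime(records["interview_date"].to_numpy()),
            "num": weights * flagged,
            "den": weights,
        }
    )
    daily = tmp.groupby(["date", "area_id"])[["num", "den"]].sum()
    num = daily["num"].unstack("area_id")
    den = daily["den"].unstack("area_id")
    if index is None:
        index = pd.date_range(num.index.min(), num.index.max(), freq="D")
    num = num.reindex(index).fillna(0.0)
    den = den.reindex(index).fillna(0.0)
    num_roll = num.rolling(window=d, min_periods=1).sum()
    den_roll = den.rolling(window=d, min_periods=1).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = num_roll / den_roll
    prev = prev.where(den_roll > 0)
    prev.index.name = "date"
    prev.columns.name = "area_id"
    return prev


def interpolate_gaps(series: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Linearly interpolate interior missing values of daily series.

    Leading and trailing gaps are left missing: linear interpolation is
    defined only between two observations.  Observed values are unchanged.
    Raises if any series has fewer than two observations.
    """
    frame = series.to_frame() if isinstance(series, pd.Series) else series
    n_obs = frame.notna().sum()
    if (n_obs < 2).any():
        bad = list(n_obs.index[n_obs < 2])
        raise ValueError(f"series with fewer than two observed values: {bad}")
    out = frame.interpolate(method="linear", limit_area="inside")
    if isinstance(series, pd.Series):
        return out.iloc[:, 0]
    return out
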