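"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: patterns
are extracted window by window, weighted shares recomputed day by day.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd


def brute_force_patterns(x, m, tau=1):
    """Sort every window independently; stable ties by temporal order."""
    x = list(x)
    span = (m - 1) * tau
    counts: Counter = Counter()
    for i in range(len(x) - span):
        window = [x[i + j * tau] for j in range(m)]
        pattern = tuple(sorted(range(m), key=lambda j: (window[j], j)))
        counts[pattern] += 1
    return dict(counts)


def brute_force_entropy(counts, m, normalized=True):
    n = sum(counts.values())
    h = -sum((c / n) * math.log(c / n) for c in counts.values() if c > 0)
    if normalized:
        h /= math.log(math.factorial(m))
    return h


def brute_force_prevalence(records: pd.DataFrame, d: int, flagged) -> pd.DataFrame:
    """Day-by-day weighted share over the half-open window (t-d, t]."""
    recs = records.copy()
    recs["flag"] = np.asarray(flagged, dtype=float)
    recs["w"] = recs["weight_pop"] * recs["weight_demo"]
    recs["interview_date"] = pd.to_datetime(recs["interview_date"])
    days = pd.date_range(
        recs["interview_date"].min(), recs["interview_date"].max(), freq="D"
    )
    areas = sorted(recs["area_id"].unique())
    out = pd.DataFrame(index=days, columns=areas, dtype=float)
    for area in areas:
        sub = recs[recs["area_id"] == area]
        for t in days:
            lo = t - pd.Timedelta(days=d)
            mask = (sub["interview_date"] > lo) & (sub["interview_date"] <= t)
            win = sub[mask]
            if len(win) == 0:
                continue
            out.loc[t, area] = float(
                (win["w"] * win["flag"]).sum() / win["w"].sum()
            )
    return out


def brute_force_r2_mse(y, yhat):
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    mse = float(np.mean((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return r2, mse
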