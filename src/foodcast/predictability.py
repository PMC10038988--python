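"""Intrinsic predictability of time series via permutation entropy.

A real-valued series is symbolised Bandt–Pompe style: every window of
``m`` values spaced ``tau`` apart is mapped to the permutation that sorts
it ascending (ties broken by temporal order).  The Shannon entropy of the
resulting ordinal-pattern distribution,

    H = -sum_pi p_pi * log(p_pi),

normalised by log(m!), measures complexity on [0, 1]; the predictability
is chi = 1 - H.  A periodic series concentrates on few patterns (chi near
1); white noise spreads uniformly over all m! patterns (chi near 0).
Because the symbols depend only on rank order, chi is invariant to
positive affine rescaling of the series.

:func:`predictability_profile` reproduces the windowed analysis used for
noisy prevalence series: chi is averaged over many randomly placed
windows of each length L = 10..100, giving a profile of short-timescale
predictability as a function of the observation span.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial, lgamma, log
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OrdinalPatternDistribution",
    "ordinal_patterns",
    "permutation_entropy",
    "predictability",
    "predictability_profile",
]


@dataclass(frozen=True)
class OrdinalPatternDistribution:
    """Counts of ordinal patterns (permutations of 0..m-1) in a series."""

    m: int
    tau: int
    counts: Mapping[tuple[int, ...], int]

    @property
    def n_windows(self) -> int:
        return int(sum(self.counts.values()))

    def probabilities(self) -> np.ndarray:
        n = self.n_windows
        if n == 0:
            raise ValueError("empty pattern distribution")
        return np.asarray(list(self.counts.values()), dtype=float) / n


def _pattern_matrix(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Ordinal pattern of every valid window; shape (n_windows, m).

    Pattern = stable argsort of the window, so equal values keep temporal
    order (the deterministic tie-break convention).
    """
    span = (m - 1) * tau + 1
    if m < 2:
        raise ValueError("embedding dimension m must be >= 2")
    if tau < 1:
        raise ValueError("time delay tau must be >= 1")
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if np.isnan(x).any():
        raise ValueError("series contains missing values; interpolate first")
    if x.size < span:
        raise ValueError(
            f"series of length {x.size} too short: need at least {span} "
            f"values for m={m}, tau={tau}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(x, span)[:, ::tau]
    return np.argsort(windows, axis=1, kind="stable")


def ordinal_patterns(
    series: Sequence[float] | np.ndarray, m: int, tau: int = 1
) -> OrdinalPatternDistribution:
    """Count the ordinal patterns of all length-m, delay-tau windows."""
    x = np.asarray(series, dtype=float)
    pats = _pattern_matrix(x, m, tau)
    uniq, cnt = np.unique(pats, axis=0, return_counts=True)
    counts = {tuple(int(v) for v in row): int(c) for row, c in zip(uniq, cnt)}
    return OrdinalPatternDistribution(m=m, tau=tau, counts=counts)


def permutation_entropy(
    dist: OrdinalPatternDistribution, normalized: bool = True
) -> float:
    """Shannon entropy of an ordinal-pattern distribution.

    Natural log, with the 0*log(0) = 0 convention.  When ``normalized``,
    the entropy is divided by log(m!) so H lies in [0, 1].
    """
    p = dist.probabilities()
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if normalized:
        h /= log(factorial(dist.m))
    return h


def predictability(h_normalized: float) -> float:
    """Predictability chi = 1 - H for a normalised entropy H in [0, 1]."""
    if not 0.0 <= h_normalized <= 1.0 + 1e-12:
        raise ValueError(
            f"H={h_normalized!r} outside [0, 1]; pass the normalised entropy"
        )
    return 1.0 - min(h_normalized, 1.0)


def _encode_patterns(pats: np.ndarray, m: int) -> tuple[np.ndarray, int]:
    """Map pattern rows to dense integer codes (0..n_distinct-1)."""
    base = np.asarray([m**j for j in range(m)])
    raw = pats @ base
    _, codes = np.unique(raw, return_inverse=True)
    return codes, int(codes.max()) + 1 if codes.size else 0


def _window_entropies(
    codes: np.ndarray, starts: np.ndarray, n_patterns: int, n_codes: int, m: int
) -> np.ndarray:
    """Normalised H of ``n_patterns`` consecutive patterns from each start."""
    idx = starts[:, None] + np.arange(n_patterns)[None, :]
    mat = codes[idx]
    rows = np.arange(len(starts))[:, None]
    flat = mat + rows * n_codes
    counts = np.bincount(flat.ravel(), minlength=len(starts) * n_codes)
    counts = counts.reshape(len(starts), n_codes).astype(float)
    p = counts / n_patterns
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return -plogp.sum(axis=1) / lgamma(m + 1)


def predictability_profile(
    series: pd.DataFrame | Mapping[str, Sequence[float]] | Sequence[float],
    window_lengths: Iterable[int] = range(10, 101),
    n_samples: int = 1000,
    m: int = 3,
    tau: int = 1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Mean predictability and interquartile band vs window length.

    For each window length ``L``, ``n_samples`` start points are drawn
    from each series (uniformly without replacement when enough valid
    starts exist, otherwise with replacement), the normalised permutation
    entropy of each window is computed, and chi = 1 - H is aggregated
    across all windows of all series.

    Parameters
    ----------
    series
        A single sequence, a mapping name -> sequence, or a wide DataFrame
        (columns = areas).  All series must be free of NaN.
    window_lengths
        Lengths L to profile (each must satisfy L >= (m-1)*tau + 2 and
        L <= shortest series).
    n_samples
        Random window placements per series and length.
    m, tau
        Embedding dimension and time delay.  A guard requires
        m! <= min(L) so each window can in principle visit every
        pattern.
    seed
        Integer seed or Generator; the profile is deterministic given it.

    Returns
    -------
    DataFrame with columns ``window_length``, ``mean_chi``, ``q25``,
    ``q75``, ``n_windows``.
    """
    if isinstance(series, pd.DataFrame):
        columns = {str(c): series[c].to_numpy(dtype=float) for c in series.columns}
    elif isinstance(series, Mapping):
        columns = {str(k): np.asarray(v, dtype=float) for k, v in series.items()}
    else:
        columns = {"series": np.asarray(series, dtype=float)}
    lengths = sorted(int(length) for length in window_lengths)
    if not lengths:
        raise ValueError("window_lengths is empty")
    if factorial(m) > lengths[0]:
        raise ValueError(
            f"m={m} too large for smallest window {lengths[0]}: need m! <= L"
        )
    span = (m - 1) * tau
    shortest = min(x.size for x in columns.values())
    if shortest <= lengths[-1]:
        raise ValueError(
            f"series of length {shortest} must exceed the largest window "
            f"{lengths[-1]}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    encoded: dict[str, tuple[np.ndarray, int]] = {}
    for name, x in columns.items():
        pats = _pattern_matrix(x, m, tau)
        encoded[name] = _encode_patterns(pats, m)

    records = []
    for length in lengths:
        n_patterns = length - span  # patterns fully inside a length-L window
        chis = []
        for name, x in columns.items():
            codes, n_codes = encoded[name]
            n_starts = x.size - length + 1
            if n_starts >= n_samples:
                starts = rng.choice(n_starts, size=n_samples, replace=False)
            else:
                starts = rng.integers(0, n_starts, size=n_samples)
            h = _window_entropies(codes, starts, n_patterns, n_codes, m)
            chis.append(1.0 - np.minimum(h, 1.0))
        chi = np.concatenate(chis)
        records.append(
            {
                "window_length": length,
                "mean_chi": float(chi.mean()),
                "q25": float(np.quantile(chi, 0.25)),
                "q75": float(np.quantile(chi, 0.75)),
                "n_windows": int(chi.size),
            }
        )
    return pd.DataFrame.from_records(records)
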