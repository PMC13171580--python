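"""Nonparametric rest-activity rhythm metrics.

Interdaily stability (IS) and intradaily variability (IV) are computed on
hourly bins; L5/M10 (least-active 5 h, most-active 10 h) and relative
amplitude (RA) are computed from the averaged 24-h minute profile, scanning
all 1,440 circularly wrapped windows.  L5 start time is expressed as signed
hours from midnight in [-12, 12) because the least-active period typically
spans midnight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import MINUTES_PER_DAY, EpochSeries, valid_day_mask

L5_WINDOW_MIN = 5 * 60
M10_WINDOW_MIN = 10 * 60


class IncompleteProfileError(ValueError):
    """A minute-of-day slot has no contributing observations."""


class InsufficientDataError(ValueError):
    """Too few hourly values for IS/IV."""


@dataclass
class NonparamMetrics:
    IS: float
    IV: float
    L5: float
    M10: float
    RA: float
    L5_start: float  # signed hours from midnight, [-12, 12)
    M10_start: float  # hours, [0, 24)
    degenerate: bool = False


def average_day_profile(
    series: EpochSeries,
    exclude_imputed: bool = False,
    valid_days_only: bool = True,
) -> np.ndarray:
    """Average 24-h profile: one mean activity value per minute of day.

    Imputed minutes contribute by default (they were filled upstream); set
    ``exclude_imputed`` for a sensitivity variant.  Raises if any slot ends
    up with zero contributing observations.
    """
    mask = valid_day_mask(series) if valid_days_only else np.ones(len(series), bool)
    if exclude_imputed:
        mask = mask & ~series.imputed
    if not mask.any():
        raise IncompleteProfileError("no contributing minutes")
    mod = series.minute_of_day()[mask]
    vals = series.values[mask]
    sums = np.bincount(mod, weights=vals, minlength=MINUTES_PER_DAY)
    counts = np.bincount(mod, minlength=MINUTES_PER_DAY)
    if np.any(counts == 0):
        raise IncompleteProfileError(
            f"{int((counts == 0).sum())} minute slots have no observations"
        )
    return sums / counts


def _window_means(profile: np.ndarray, width: int) -> np.ndarray:
    """Mean of every circularly wrapped window of ``width`` minutes."""
    ext = np.concatenate([profile, profile[: width - 1]])
    csum = np.concatenate([[0.0], np.cumsum(ext)])
    return (csum[width:] - csum[:-width]) / width


def l5_m10(profile: np.ndarray) -> tuple[float, float, float, float]:
    """L5/M10 window scan over the 1,440-slot average day profile.

    Returns (L5, L5_start, M10, M10_start).  L5_start is signed hours from
    midnight in [-12, 12); M10_start is hours in [0, 24).  Ties break to
    the earliest start after midnight.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (MINUTES_PER_DAY,):
        raise ValueError("profile must have 1,440 slots")
    w5 = _window_means(profile, L5_WINDOW_MIN)
    w10 = _window_means(profile, M10_WINDOW_MIN)
    i5 = int(np.argmin(w5))  # argmin/argmax take the first (earliest) index on ties
    i10 = int(np.argmax(w10))
    l5 = float(w5[i5])
    m10 = float(w10[i10])
    l5_start = i5 / 60.0
    if l5_start >= 12.0:
        l5_start -= 24.0
    m10_start = i10 / 60.0
    return l5, l5_start, m10, m10_start


def relative_amplitude(l5: float, m10: float) -> float:
    """RA = (M10 - L5)/(M10 + L5); 0 for a flat profile."""
    denom = m10 + l5
    if denom <= 0:
        return 0.0
    return (m10 - l5) / denom


def hourly_bins(series: EpochSeries, valid_days_only: bool = True) -> np.ndarray:
    """Rebin a 1-min series to consecutive hourly means over valid days."""
    mask = valid_day_mask(series) if valid_days_only else np.ones(len(series), bool)
    vals = series.values[mask]
    n_hours = len(vals) // 60
    if n_hours == 0:
        return np.empty(0)
    return vals[: n_hours * 60].reshape(n_hours, 60).mean(axis=1)


def is_iv(hourly: np.ndarray, period: int = 24) -> tuple[float, float, bool]:
    """Interdaily stability and intradaily variability from hourly values.

    IS = (N * sum_h (xbar_h - xbar)^2) / (p * sum_i (x_i - xbar)^2)
    IV = (N * sum_{i>=2} (x_i - x_{i-1})^2) / ((N-1) * sum_i (x_i - xbar)^2)

    with N hourly values and p = 24 hourly slots.  A constant series has
    0/0 in both ratios; the convention here is IS = IV = 0 with a
    degeneracy flag.  Returns (IS, IV, degenerate).
    """
    x = np.asarray(hourly, dtype=float)
    n = len(x)
    if n < 2 * period:
        raise InsufficientDataError(f"need >= {2 * period} hourly values, got {n}")
    xbar = x.mean()
    ss_total = float(np.sum((x - xbar) ** 2))
    if ss_total == 0.0:
        return 0.0, 0.0, True
    slots = np.arange(n) % period
    slot_means = np.bincount(slots, weights=x, minlength=period) / np.bincount(
        slots, minlength=period
    )
    is_val = (n * float(np.sum((slot_means - xbar) ** 2))) / (period * ss_total)
    iv_val = (n * float(np.sum(np.diff(x) ** 2))) / ((n - 1) * ss_total)
    return is_val, iv_val, False


def nonparam_metrics(
    series: EpochSeries, exclude_imputed: bool = False
) -> NonparamMetrics:
    """All seven nonparametric metrics for one participant's 1-min series."""
    profile = average_day_profile(series, exclude_imputed=exclude_imputed)
    l5, l5_start, m10, m10_start = l5_m10(profile)
    ra = relative_amplitude(l5, m10)
    is_val, iv_val, degen = is_iv(hourly_bins(series))
    return NonparamMetrics(
        IS=is_val, IV=iv_val, L5=l5, M10=m10, RA=ra,
        L5_start=l5_start, M10_start=m10_start, degenerate=degen,
    )
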