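"""Day-of-year climatologies, daily anomalies and trailing 7-day aggregates.

A climatology is the per-day-of-year mean across all years of record; a
daily anomaly is the observation minus the climatological mean for its
calendar day.  Weekly quantities are overlapping, daily-stepped trailing
windows covering days t-6..t inclusive, summed for counts and averaged
for temperatures.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .series import DailySeries

__all__ = [
    "Climatology",
    "AnomalySeries",
    "WeeklyAnomaly",
    "build_climatology",
    "compute_anomalies",
    "weekly_aggregate",
]

N_DOY = 366
WINDOW = 7


@dataclass(frozen=True)
class Climatology:
    """366 day-of-year reference means (index 0 is doy 1).

    ``counts_per_doy[d]`` is the number of observations contributing to
    ``doy_means[d]``; doy 60 (Feb 29) normally has fewer contributing
    years.  A doy with zero contributions has a NaN mean.
    """

    doy_means: np.ndarray
    counts_per_doy: np.ndarray
    smooth_halfwidth: int = 0

    def __post_init__(self) -> None:
        if self.doy_means.shape != (N_DOY,) or self.counts_per_doy.shape != (N_DOY,):
            raise ValueError("climatology arrays must have length 366")
        has_data = self.counts_per_doy > 0
        if np.any(~np.isfinite(self.doy_means[has_data])):
            raise ValueError("non-finite mean on a populated day-of-year")

    def lookup(self, doy: np.ndarray) -> np.ndarray:
        return self.doy_means[np.asarray(doy) - 1]


@dataclass(frozen=True)
class AnomalySeries:
    dates: pd.DatetimeIndex
    anomalies: np.ndarray

    def __len__(self) -> int:
        return len(self.dates)


@dataclass(frozen=True)
class WeeklyAnomaly:
    """Trailing 7-day aggregate of daily anomalies, one value per end-day.

    ``values[t]`` covers days t-6..t and is NaN for the first six days and
    for any window containing a missing anomaly.  ``stat`` records whether
    the window was summed ("sum", counts) or averaged ("mean",
    temperatures).
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    stat: str

    def __len__(self) -> int:
        return len(self.dates)

    def eligible(self) -> np.ndarray:
        return np.isfinite(self.values)

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates)


def _span_days(dates: pd.DatetimeIndex) -> int:
    return (dates[-1] - dates[0]).days + 1


def build_climatology(series: DailySeries, smooth_halfwidth: int = 0) -> Climatology:
    """Mean observed value for each day of the year.

    With ``smooth_halfwidth = h > 0`` the mean for day-of-year d pools all
    observations whose day-of-year lies within d +/- h, wrapping across the
    year boundary.  This is the documented mitigation for the small Feb 29
    sample.
    """
    if smooth_halfwidth < 0:
        raise ValueError("smooth_halfwidth must be >= 0")
    if _span_days(series.dates) < 2 * 365:
        raise ValueError("climatology requires at least 2 full years of data")

    doy = series.doy
    valid = np.isfinite(series.values)
    sums = np.bincount(doy[valid] - 1, weights=series.values[valid], minlength=N_DOY)
    counts = np.bincount(doy[valid] - 1, minlength=N_DOY)

    if smooth_halfwidth > 0:
        h = smooth_halfwidth
        # circular pooling over day-of-year
        psums = np.concatenate([sums[-h:], sums, sums[:h]])
        pcnts = np.concatenate([counts[-h:], counts, counts[:h]])
        kernel = np.ones(2 * h + 1)
        sums = np.convolve(psums, kernel, mode="valid")
        counts = np.convolve(pcnts, kernel, mode="valid")

    counts = counts.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return Climatology(means, counts, smooth_halfwidth=smooth_halfwidth)


def compute_anomalies(series: DailySeries, clim: Climatology) -> AnomalySeries:
    """Observation minus the climatological mean for its day-of-year.

    Missing observations (and doys with an empty climatology) propagate
    as NaN.
    """
    anoms = series.values - clim.lookup(series.doy)
    return AnomalySeries(series.dates, anoms)


def weekly_aggregate(anoms: AnomalySeries, stat: str, offset: int = 0) -> WeeklyAnomaly:
    """Trailing 7-day sum or mean of daily anomalies.

    ``offset`` shifts the window back in time: with ``offset = k`` the value
    reported for day t covers days t-6-k..t-k (``offset = 1`` gives a
    strictly preceding week).  Windows touching a missing day are NaN.
    """
    if stat not in ("sum", "mean"):
        raise ValueError(f"stat must be 'sum' or 'mean', got {stat!r}")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if len(anoms) < WINDOW + offset:
        raise ValueError(f"need at least {WINDOW + offset} days of data")

    s = pd.Series(anoms.anomalies, index=anoms.dates)
    rolled = s.rolling(WINDOW, min_periods=WINDOW)
    out = (rolled.sum() if stat == "sum" else rolled.mean())
    if offset:
        out = out.shift(offset)
    return WeeklyAnomaly(anoms.dates, out.to_numpy(), stat)
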