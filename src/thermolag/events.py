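"""Percentile event classification and contingency analysis of weekly anomalies.

High-end / low-end event weeks are trailing 7-day count anomalies at or
above the 95th / at or below the 5th percentile.  Temperature weeks in
the selected months are cut into cool / normal / warm categories by
share-calibrated percentiles, and the two label sets are crossed into a
3x3 contingency table with column percentages.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anomaly import WeeklyAnomaly

__all__ = [
    "EventThresholds",
    "TempCategorySpec",
    "ContingencyTable",
    "classify_suicide_weeks",
    "monthly_event_profile",
    "select_months",
    "greatest_departure",
    "classify_temperature_weeks",
    "contingency",
]

SUICIDE_CLASSES = ("high", "normal", "low")
TEMP_CATEGORIES = ("cool", "normal", "warm")
MONTH_NAMES = ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
               "Jul", "Aug", "Sep", "Oct", "Nov", "Dec")


@dataclass(frozen=True)
class EventThresholds:
    """Realized weekly-anomaly values at the low and high percentile cuts."""

    low_cut: float
    high_cut: float
    low_q: float = 5.0
    high_q: float = 95.0

    def __post_init__(self) -> None:
        if self.low_cut > self.high_cut:
            raise ValueError("low_cut must not exceed high_cut")


@dataclass(frozen=True)
class TempCategorySpec:
    """Share-calibrated cool/warm category definition.

    ``cool_share`` of days get the "cool" label (lowest values) and
    ``warm_share`` the "warm" label (highest values); the remainder is
    "normal".  ``variable`` records which weekly temperature anomaly the
    categories are cut on.
    """

    cool_share: float = 0.14
    warm_share: float = 0.10
    variable: str = "greatest_departure"

    def __post_init__(self) -> None:
        if not (self.cool_share > 0 and self.warm_share > 0):
            raise ValueError("cool_share and warm_share must be > 0")
        if self.cool_share + self.warm_share >= 1:
            raise ValueError("cool_share + warm_share must be < 1")
        if self.variable not in ("min", "max", "greatest_departure"):
            raise ValueError(f"unknown variable {self.variable!r}")


def _round_half_away(x: np.ndarray, decimals: int = 1) -> np.ndarray:
    f = 10.0 ** decimals
    return np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f


@dataclass(frozen=True)
class ContingencyTable:
    """3x3 day counts (event class x temperature category) and column %.

    Column percentages are 100*count/column-total, rounded half away from
    zero to one decimal; an empty column's percentages are NaN.
    """

    counts: pd.DataFrame
    col_pct: pd.DataFrame

    @classmethod
    def from_counts(cls, counts: pd.DataFrame | np.ndarray) -> "ContingencyTable":
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(np.asarray(counts),
                                  index=list(SUICIDE_CLASSES),
                                  columns=list(TEMP_CATEGORIES))
        arr = counts.to_numpy(dtype=float)
        if arr.shape != (3, 3):
            raise ValueError("contingency counts must be 3x3")
        if np.any(arr < 0) or np.any(arr != np.round(arr)):
            raise ValueError("contingency counts must be non-negative integers")
        totals = arr.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * arr / np.where(totals > 0, totals, 1), np.nan)
        pct = _round_half_away(pct, 1)
        return cls(counts.astype(int),
                   pd.DataFrame(pct, index=counts.index, columns=counts.columns))

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def column_shares(self) -> pd.Series:
        """Share of classified days per temperature category (fractions)."""
        tot = self.counts.sum(axis=0)
        return tot / tot.sum()


def classify_suicide_weeks(weekly: WeeklyAnomaly, low_q: float = 5.0,
                           high_q: float = 95.0) -> tuple[pd.Series, EventThresholds]:
    """Label each eligible day high / low / normal by weekly-anomaly percentile.

    Thresholds are the ``low_q`` and ``high_q`` percentiles (linear
    interpolation between order statistics) of all eligible weekly values;
    a day is "high" when its value is >= the high cut and "low" when
    <= the low cut.  If the two cuts coincide (degenerate, e.g. all values
    equal) every day is "normal".  Ineligible days get NaN labels.
    """
    vals = weekly.values
    eligible = np.isfinite(vals)
    n = int(eligible.sum())
    if n == 0:
        raise ValueError("no eligible weekly values")
    if n < 40:
        raise ValueError(f"only {n} eligible days; need >= 40 for percentile cuts")
    if not (0 <= low_q < high_q <= 100):
        raise ValueError("require 0 <= low_q < high_q <= 100")

    low_cut, high_cut = np.percentile(vals[eligible], [low_q, high_q])
    labels = np.full(len(vals), None, dtype=object)
    if high_cut > low_cut:
        labels[eligible] = "normal"
        labels[eligible & (vals >= high_cut)] = "high"
        labels[eligible & (vals <= low_cut)] = "low"
    else:
        labels[eligible] = "normal"  # degenerate tie: no event weeks
    return (pd.Series(labels, index=weekly.dates),
            EventThresholds(float(low_cut), float(high_cut), low_q, high_q))


def monthly_event_profile(weekly_temp: WeeklyAnomaly, labels: pd.Series) -> pd.DataFrame:
    """Mean weekly temperature anomaly per calendar month and event class.

    Months index the window end-day.  Returns a 12x3 frame with columns
    high / low / other; cells with no contributing days are NaN.
    """
    lab = labels.reindex(weekly_temp.dates)
    month = weekly_temp.dates.month
    cls = lab.to_numpy(dtype=object)
    cls = np.where(pd.isna(cls), None, cls)
    cls = np.where(cls == "normal", "other", cls)

    out = pd.DataFrame(np.nan, index=range(1, 13), columns=["high", "low", "other"])
    ok = np.isfinite(weekly_temp.values) & (cls != None)  # noqa: E711
    for m in range(1, 13):
        for c in out.columns:
            sel = ok & (month == m) & (cls == c)
            if sel.any():
                out.loc[m, c] = weekly_temp.values[sel].mean()
    return out


def select_months(profile: pd.DataFrame, k: int = 4,
                  override: Sequence[int] | None = None) -> list[int]:
    """Months with the largest |mean(high) - mean(low)| anomaly difference.

    Months whose high or low cell is empty are excluded from ranking.  An
    explicit ``override`` month list short-circuits the ranking.  Ties are
    broken toward the earlier month.
    """
    if override is not None:
        months = sorted(set(int(m) for m in override))
        if any(m < 1 or m > 12 for m in months):
            raise ValueError("override months must be in 1..12")
        return months
    diff = (profile["high"] - profile["low"]).abs()
    diff = diff.dropna()
    if len(diff) < k:
        raise ValueError(f"only {len(diff)} months have both high and low cells; "
                         f"cannot select {k}")
    order = sorted(diff.index, key=lambda m: (-diff[m], m))
    return sorted(order[:k])


def greatest_departure(weekly_max: WeeklyAnomaly, weekly_min: WeeklyAnomaly) -> WeeklyAnomaly:
    """Per day, whichever weekly anomaly (max- or min-temperature) has the
    larger absolute value, sign preserved.

    Exact ties go to the max-temperature variable.  A missing value on
    either side yields a missing result.
    """
    if not (weekly_max.dates == weekly_min.dates).all():
        raise ValueError("weekly series must share a calendar")
    a, b = weekly_max.values, weekly_min.values
    out = np.where(np.abs(a) >= np.abs(b), a, b)
    out = np.where(np.isfinite(a) & np.isfinite(b), out, np.nan)
    return WeeklyAnomaly(weekly_max.dates, out, "mean")


def classify_temperature_weeks(weekly_temp: WeeklyAnomaly, spec: TempCategorySpec,
                               months: Iterable[int] | None = None) -> pd.Series:
    """Cut weekly temperature anomalies into cool / normal / warm.

    Restricted to the window end-days whose month is in ``months`` (all
    months if None).  Cool = values at or below the ``cool_share``
    quantile of the restricted subset; warm = values at or above the
    ``1 - warm_share`` quantile; remainder normal.  Days outside the
    subset, or with missing values, get NaN labels.
    """
    vals = weekly_temp.values
    sel = np.isfinite(vals)
    if months is not None:
        msel = np.isin(weekly_temp.dates.month, list(months))
        sel &= msel
    if not sel.any():
        raise ValueError("selected-month subset is empty")

    sub = vals[sel]
    cool_cut = np.quantile(sub, spec.cool_share)
    warm_cut = np.quantile(sub, 1.0 - spec.warm_share)
    labels = np.full(len(vals), None, dtype=object)
    labels[sel] = "normal"
    labels[sel & (vals <= cool_cut)] = "cool"
    # warm wins a (measure-zero) overlap with cool
    labels[sel & (vals >= warm_cut)] = "warm"
    return pd.Series(labels, index=weekly_temp.dates)


def contingency(suicide_labels: pd.Series, temp_labels: pd.Series) -> ContingencyTable:
    """Cross the two label sets into the 3x3 day-count table.

    Only days carrying both labels are tabulated.
    """
    idx = suicide_labels.index.intersection(temp_labels.index)
    s = suicide_labels.reindex(idx)
    t = temp_labels.reindex(idx)
    ok = s.notna() & t.notna()
    counts = pd.DataFrame(0, index=list(SUICIDE_CLASSES), columns=list(TEMP_CATEGORIES))
    ct = pd.crosstab(s[ok], t[ok])
    for r in ct.index:
        for c in ct.columns:
            counts.loc[r, c] = int(ct.loc[r, c])
    return ContingencyTable.from_counts(counts)
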