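"""Synthetic daily temperature / count series with a known exposure effect.

Temperatures are a sinusoidal annual cycle plus a shared AR(1) anomaly
process (the shared anomaly keeps tmax >= tmin structurally); counts are
Poisson with a log-rate combining a seasonal cycle, day-of-week offsets
and a known lag-distributed effect of the temperature anomaly, so the
whole analysis pipeline can be exercised against recoverable truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import DailySeries, daily_index, stable_doy

__all__ = ["SimConfig", "simulate_temperature", "simulate_counts",
           "simulate_dataset", "preset", "PRESETS"]

PERIOD = 365.25


def _seasonal_cycle(doy: np.ndarray, mean: float, amp: float, phase: float) -> np.ndarray:
    return mean + amp * np.cos(2.0 * math.pi * (doy - phase) / PERIOD)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic generator.

    ``theta`` is the cumulative log-rate-ratio per degC of temperature
    anomaly, distributed over lags 0..L by the non-negative ``lag_weights``
    (which sum to 1).  One integer ``seed`` drives the run; temperature and
    counts use independent substreams spawned from it.
    """

    n_years: int = 4
    start_year: int = 2000
    tmean_max: float = 13.2
    tmean_min: float = 3.6
    amp_max: float = 14.0
    amp_min: float = 13.0
    phase: float = 200.0
    ar_rho: float = 0.7
    ar_sigma: float = 3.0
    base_rate: float = 1.2
    season_amp: float = 0.0
    dow_effects: tuple[float, ...] = (0.0,) * 7  # Monday-first (pandas weekday)
    theta: float = 0.0
    lag_weights: tuple[float, ...] = field(
        default_factory=lambda: tuple([1 / 7] * 7))
    seed: int = 0

    def __post_init__(self) -> None:
        scalars = ["tmean_max", "tmean_min", "amp_max", "amp_min", "phase",
                   "ar_rho", "ar_sigma", "base_rate", "season_amp", "theta"]
        for name in scalars:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for field {name!r}")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if not (0 <= self.ar_rho < 1):
            raise ValueError("ar_rho must lie in [0, 1)")
        if self.ar_sigma < 0:
            raise ValueError("ar_sigma must be >= 0")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if len(self.dow_effects) != 7 or not np.all(np.isfinite(self.dow_effects)):
            raise ValueError("dow_effects must be 7 finite log-rate offsets")
        w = np.asarray(self.lag_weights, dtype=float)
        if w.ndim != 1 or len(w) == 0 or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("lag_weights must be non-negative and finite")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag_weights must sum to 1 within 1e-12")
        # the shared-anomaly construction needs the noise-free cycles ordered
        if self.tmean_max - self.tmean_min < abs(self.amp_max - self.amp_min):
            raise ValueError("tmean_max - tmean_min must be >= |amp_max - amp_min| "
                             "so that tmax >= tmin on every day")

    @property
    def max_lag(self) -> int:
        return len(self.lag_weights) - 1

    def dates(self) -> pd.DatetimeIndex:
        return daily_index(f"{self.start_year}-01-01",
                           f"{self.start_year + self.n_years - 1}-12-31")

    def _streams(self) -> tuple[np.random.Generator, np.random.Generator]:
        temp_ss, count_ss = np.random.SeedSequence(self.seed).spawn(2)
        return np.random.default_rng(temp_ss), np.random.default_rng(count_ss)


def _ar1(rng: np.random.Generator, n: int, rho: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) path: a_t = rho*a_{t-1} + N(0, sigma^2)."""
    if sigma == 0.0:
        return np.zeros(n)
    a = np.empty(n)
    a[0] = rng.normal(0.0, sigma / math.sqrt(1.0 - rho * rho))
    eps = rng.normal(0.0, sigma, size=n - 1)
    for t in range(1, n):
        a[t] = rho * a[t - 1] + eps[t - 1]
    return a


def simulate_temperature(config: SimConfig) -> tuple[DailySeries, DailySeries]:
    """Daily (tmax, tmin) series: annual cycles plus one shared AR(1) anomaly."""
    dates = config.dates()
    doy = stable_doy(dates)
    rng_temp, _ = config._streams()
    anom = _ar1(rng_temp, len(dates), config.ar_rho, config.ar_sigma)
    tmax = _seasonal_cycle(doy, config.tmean_max, config.amp_max, config.phase) + anom
    tmin = _seasonal_cycle(doy, config.tmean_min, config.amp_min, config.phase) + anom
    return (DailySeries(dates, tmax, name="tmax"),
            DailySeries(dates, tmin, name="tmin"))


def temperature_anomaly(tmax: DailySeries, config: SimConfig) -> np.ndarray:
    """Deviation of tmax from its own noise-free cycle (the AR(1) process)."""
    cycle = _seasonal_cycle(stable_doy(tmax.dates), config.tmean_max,
                            config.amp_max, config.phase)
    return tmax.values - cycle


def simulate_counts(temps: tuple[DailySeries, DailySeries],
                    config: SimConfig) -> DailySeries:
    """Poisson daily counts driven by season, day-of-week and lagged anomaly.

    log-rate(t) = log(base_rate) + season_amp*cos(2*pi*(doy-phase)/365.25)
                  + dow_effect(t) + theta * sum_l w_l * anomaly(t-l).
    The first L days use truncated, renormalized lag weights so the series
    keeps its full length.
    """
    tmax, tmin = temps
    if not tmax.same_calendar(tmin):
        raise ValueError("tmax and tmin calendars differ")
    dates = tmax.dates
    expected = config.dates()
    if len(dates) != len(expected) or not (dates == expected).all():
        raise ValueError("temperature calendar does not match config")
    doy = stable_doy(dates)
    n = len(dates)
    anom = temperature_anomaly(tmax, config)

    w = np.asarray(config.lag_weights, dtype=float)
    L = config.max_lag
    lagged = np.zeros(n)
    for l, wl in enumerate(w):
        lagged[l:] += wl * anom[: n - l] if l else wl * anom
    # renormalize the truncated head so early days use a proper average
    head = np.cumsum(w)[:L]
    for t in range(min(L, n)):
        s = 0.0
        for l in range(t + 1):
            s += w[l] * anom[t - l]
        lagged[t] = s / head[t] if head[t] > 0 else 0.0

    log_rate = (math.log(config.base_rate)
                + config.season_amp * np.cos(2.0 * math.pi * (doy - config.phase) / PERIOD)
                + np.asarray(config.dow_effects)[dates.weekday]
                + config.theta * lagged)
    _, rng_count = config._streams()
    counts = rng_count.poisson(np.exp(log_rate))
    return DailySeries(dates, counts.astype(float), kind="count", name="count")


def simulate_dataset(config: SimConfig) -> pd.DataFrame:
    """Full synthetic table with columns date, tmax, tmin, count."""
    tmax, tmin = simulate_temperature(config)
    count = simulate_counts((tmax, tmin), config)
    return pd.DataFrame({"date": tmax.dates.strftime("%Y-%m-%d"),
                         "tmax": tmax.values, "tmin": tmin.values,
                         "count": count.values.astype(int)})


PRESETS: dict[str, SimConfig] = {
    # ~1.23 events/day over 24 years at a mid-latitude station profile
    "toronto_like": SimConfig(
        n_years=24, start_year=1986,
        tmean_max=13.2, tmean_min=3.6, amp_max=14.0, amp_min=13.0,
        phase=200.0, ar_rho=0.7, ar_sigma=3.5,
        base_rate=1.23, season_amp=0.0,
        dow_effects=(0.04, 0.0, -0.02, -0.02, 0.0, -0.02, 0.02),
        theta=0.0),
    # ~0.10 events/day over 27 years at a subtropical station profile
    "jackson_like": SimConfig(
        n_years=27, start_year=1980,
        tmean_max=24.6, tmean_min=12.0, amp_max=9.0, amp_min=8.0,
        phase=200.0, ar_rho=0.65, ar_sigma=2.8,
        base_rate=0.10, season_amp=0.0,
        dow_effects=(0.04, 0.0, -0.02, -0.02, 0.0, -0.02, 0.02),
        theta=0.0),
}


def preset(name: str, **overrides) -> SimConfig:
    """Named preset configuration, optionally with field overrides."""
    try:
        cfg = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; "
                         f"choose from {sorted(PRESETS)}") from None
    return replace(cfg, **overrides) if overrides else cfg
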