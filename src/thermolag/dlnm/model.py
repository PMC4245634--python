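"""Count regression around the cross-basis, RR prediction and the AIC grid.

The full design is: intercept + cross-basis columns + a natural cubic
time spline (interior knots equally spaced over the stratum's date span;
11 / 5 / 3 knots for annual / biannual / seasonal scales) + six
day-of-week indicator contrasts (reference Sunday).  Cumulative relative
risk compares a constant exposure held over all lags against the stratum
median exposure.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..series import DailySeries
from .basis import ExposureBasisSpec, LagBasisSpec, natural_cubic_design
from .crossbasis import CrossBasisMatrix, build_cross_basis
from .glm import FitResult, fit_poisson

__all__ = ["ModelSpec", "RRCurve", "fit_count_regression",
           "predict_cumulative_rr", "aic_grid_search", "fit_strata",
           "stratum_masks", "season_of", "winter_season_year", "TIME_KNOTS"]

#: interior time-spline knot counts per analysis scale
TIME_KNOTS = {"annual": 11, "biannual": 5, "seasonal": 3, "warm_season": 5}

DOW_NAMES = ("dow_Mon", "dow_Tue", "dow_Wed", "dow_Thu", "dow_Fri", "dow_Sat")
Z_95 = 1.96

SEASON_BY_MONTH = {12: "winter", 1: "winter", 2: "winter",
                   3: "spring", 4: "spring", 5: "spring",
                   6: "summer", 7: "summer", 8: "summer",
                   9: "fall", 10: "fall", 11: "fall"}


@dataclass(frozen=True)
class ModelSpec:
    """Nuisance structure of the count regression.

    ``time_knots`` counts the *interior* knots of the natural cubic time
    spline; None derives it from ``scale`` via :data:`TIME_KNOTS`.
    """

    scale: str = "annual"
    time_knots: int | None = None
    day_of_week: bool = True
    quasi: bool = False

    def __post_init__(self) -> None:
        if self.scale not in TIME_KNOTS:
            raise ValueError(f"scale must be one of {sorted(TIME_KNOTS)}")
        if self.time_knots is not None and self.time_knots < 1:
            raise ValueError("time_knots must be >= 1")

    @property
    def n_time_knots(self) -> int:
        return self.time_knots if self.time_knots is not None else TIME_KNOTS[self.scale]


def _time_spline(day_index: np.ndarray, n_interior: int) -> np.ndarray:
    """Natural cubic spline of (scaled) time with equally spaced interior knots."""
    t = np.asarray(day_index, dtype=float)
    lo, hi = t.min(), t.max()
    u = (t - lo) / max(hi - lo, 1.0)  # scale for conditioning
    knots = np.linspace(0.0, 1.0, n_interior + 2)  # boundary + interior
    return natural_cubic_design(u, knots)


def _dow_design(dates: pd.DatetimeIndex) -> np.ndarray:
    """Six weekday indicators, reference Sunday (pandas weekday 6)."""
    wd = np.asarray(dates.weekday)
    return np.column_stack([(wd == d).astype(float) for d in range(6)])


def _assemble_design(counts: DailySeries, cb: CrossBasisMatrix, model: ModelSpec,
                     rows: np.ndarray) -> tuple[np.ndarray, np.ndarray, list[str], dict]:
    """Design matrix and response restricted to the boolean row mask."""
    if len(counts) != cb.matrix.shape[0]:
        raise ValueError("counts and cross-basis are not aligned")
    idx = np.where(rows)[0]
    y = counts.values[idx]
    blocks: list[np.ndarray] = [np.ones((len(idx), 1))]
    names: list[str] = ["intercept"]
    slices: dict[str, slice] = {"intercept": slice(0, 1)}

    cb_cols = cb.matrix[idx]
    slices["crossbasis"] = slice(1, 1 + cb_cols.shape[1])
    blocks.append(cb_cols)
    names += cb.column_names()

    start = 1 + cb_cols.shape[1]
    ts = _time_spline(idx, model.n_time_knots)
    slices["time"] = slice(start, start + ts.shape[1])
    blocks.append(ts)
    names += [f"time_s{j}" for j in range(ts.shape[1])]
    start += ts.shape[1]

    if model.day_of_week:
        dw = _dow_design(counts.dates[idx])
        slices["dow"] = slice(start, start + 6)
        blocks.append(dw)
        names += list(DOW_NAMES)

    return np.column_stack(blocks), y, names, slices


def fit_count_regression(counts: DailySeries, cb: CrossBasisMatrix,
                         model: ModelSpec,
                         rows: np.ndarray | None = None) -> FitResult:
    """Poisson log-link fit of counts on cross-basis + time spline + weekday.

    ``rows`` optionally restricts the estimation sample (boolean mask over
    days); it is intersected with the cross-basis validity mask, which
    already drops the first L days.
    """
    mask = cb.valid_rows
    if rows is not None:
        mask = mask & np.asarray(rows, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("no usable rows after applying lag/missingness masks")
    X, y, names, slices = _assemble_design(counts, cb, model, mask)
    fit = fit_poisson(X, y, names=names, quasi=model.quasi)
    return replace(fit, term_slices=dict(slices))


@dataclass(frozen=True)
class RRCurve:
    """Cumulative relative risk over an exposure grid vs. a reference value.

    RR at the reference is exactly 1 with zero SE; ``extrapolated`` flags
    grid points beyond the exposure-basis boundary knots, where the
    natural spline continues linearly.
    """

    grid: np.ndarray
    reference: float
    rr: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    extrapolated: np.ndarray

    def covers_one(self) -> np.ndarray:
        return (self.lo <= 1.0) & (1.0 <= self.hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"exposure": self.grid, "rr": self.rr,
                             "lo": self.lo, "hi": self.hi,
                             "extrapolated": self.extrapolated})


def cumulative_contrast(cb: CrossBasisMatrix, grid: np.ndarray,
                        reference: float) -> np.ndarray:
    """Contrast rows c(x): [b_j(x) - b_j(x0)] * sum_l p_k(l), flattened (j, k)."""
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    Bg = cb.exposure_spec.design(grid)
    B0 = cb.exposure_spec.design(np.array([reference]))
    s = cb.lag_sums()  # (lag_df,)
    diff = Bg - B0  # (g, J)
    return (diff[:, :, None] * s[None, None, :]).reshape(len(grid), -1)


def predict_cumulative_rr(fit: FitResult, cb: CrossBasisMatrix,
                          grid: np.ndarray | None = None,
                          reference: float | None = None) -> RRCurve:
    """Cumulative RR (all lags at a constant exposure) vs. the reference.

    The reference defaults to the median of the exposures the cross-basis
    was built on; the grid defaults to 50 points over the observed range.
    """
    x = cb.exposure[np.isfinite(cb.exposure)]
    if reference is None:
        reference = float(np.median(x))
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    grid = np.atleast_1d(np.asarray(grid, dtype=float))

    sl = fit.term_slices.get("crossbasis")
    if sl is None:
        raise ValueError("fit carries no cross-basis block")
    beta = fit.coef[sl]
    cov = fit.cov[sl, sl]

    C = cumulative_contrast(cb, grid, reference)
    log_rr = C @ beta
    var = np.einsum("gi,ij,gj->g", C, cov, C)
    se = np.sqrt(np.clip(var, 0.0, None))
    lo_b, hi_b = cb.exposure_spec.boundary
    extrap = (grid < lo_b) | (grid > hi_b)
    if extrap.any():
        warnings.warn("RR grid extends beyond the exposure boundary knots; "
                      "the natural-spline linear tail is used", stacklevel=2)
    return RRCurve(grid=grid, reference=float(reference),
                   rr=np.exp(log_rr),
                   lo=np.exp(log_rr - Z_95 * se),
                   hi=np.exp(log_rr + Z_95 * se),
                   log_rr=log_rr, se=se, extrapolated=extrap)


def aic_grid_search(counts: DailySeries, exposure: DailySeries,
                    lags: tuple[int, ...] = (3, 4, 5, 6),
                    lag_dfs: tuple[int, ...] = (2, 3, 4),
                    exp_dfs: tuple[int, ...] = (3, 4, 5, 6, 7, 8),
                    model: ModelSpec | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """One fit per admissible (lag, lag_df, exposure_df) triple.

    All fits share a common estimation sample (the first max(lags) days
    are dropped for every fit) so AIC values are comparable across lags.
    Infeasible cells (lag_df > lag) and failed fits are NaN.  Returns the
    AIC table indexed by (lag_df, exposure_df) with one column per lag,
    plus the argmin configuration.
    """
    model = model or ModelSpec()
    if not counts.same_calendar(exposure):
        raise ValueError("counts and exposure calendars differ")
    L_max = max(lags)
    n = len(counts)
    common = np.zeros(n, dtype=bool)
    common[L_max:] = True
    common &= np.isfinite(exposure.values)

    index = pd.MultiIndex.from_product([lag_dfs, exp_dfs],
                                       names=["lag_df", "exposure_df"])
    table = pd.DataFrame(np.nan, index=index, columns=list(lags))
    table.columns.name = "lag"
    best = {"aic": np.inf}
    for lag in lags:
        for lag_df in lag_dfs:
            if lag_df > lag:
                continue  # "na" cell
            l_spec = LagBasisSpec(max_lag=lag, df=lag_df)
            for exp_df in exp_dfs:
                try:
                    cb = build_cross_basis(exposure, ExposureBasisSpec(exp_df), l_spec)
                    fit = fit_count_regression(counts, cb, model, rows=common)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    warnings.warn(f"grid cell (lag={lag}, lag_df={lag_df}, "
                                  f"exp_df={exp_df}) failed: {exc}", stacklevel=2)
                    continue
                table.loc[(lag_df, exp_df), lag] = fit.aic
                if fit.aic < best["aic"]:
                    best = {"lag": lag, "lag_df": lag_df, "exp_df": exp_df,
                            "aic": fit.aic, "fit": fit, "crossbasis": cb}
    if "lag" not in best:
        raise ValueError("every grid cell failed")
    return table, best


def season_of(dates: pd.DatetimeIndex) -> np.ndarray:
    """Meteorological season labels (winter = Dec-Feb, etc.)."""
    return np.array([SEASON_BY_MONTH[m] for m in dates.month], dtype=object)


def winter_season_year(date: pd.Timestamp) -> int:
    """Starting year of the winter containing *date* (Dec attaches forward:
    1995-12-15 belongs to winter 1995/96)."""
    date = pd.Timestamp(date)
    return date.year if date.month == 12 else date.year - 1


def stratum_masks(dates: pd.DatetimeIndex, scale: str) -> dict[str, np.ndarray]:
    """Boolean day masks per stratum for the given analysis scale.

    Strata pool all years: e.g. "winter" is every Dec-Feb day on record.
    """
    month = np.asarray(dates.month)
    if scale == "annual":
        return {"all": np.ones(len(dates), dtype=bool)}
    if scale == "warm_season":
        return {"warm_season": np.isin(month, [3, 4, 5, 6, 7, 8])}
    if scale == "biannual":
        warm = np.isin(month, [3, 4, 5, 6, 7, 8])
        return {"mar_aug": warm, "sep_feb": ~warm}
    if scale == "seasonal":
        seasons = season_of(dates)
        return {s: seasons == s for s in ("winter", "spring", "summer", "fall")}
    raise ValueError(f"unknown scale {scale!r}")


def fit_strata(counts: DailySeries, exposure: DailySeries, scale: str,
               exp_df: int = 4, lag_df: int = 2, max_lag: int = 6,
               grid_points: int = 50, quasi: bool = False
               ) -> dict[str, tuple[FitResult, RRCurve]]:
    """Per-stratum DLNM fits with stratum-specific median references.

    The cross-basis (and hence each day's lag window) is built on the full
    contiguous series; only the estimation rows are restricted to the
    stratum.  Exposure-spline knots and the reference median come from the
    stratum's own exposures.  Strata too small for the design are skipped
    with a warning.
    """
    if not counts.same_calendar(exposure):
        raise ValueError("counts and exposure calendars differ")
    model = ModelSpec(scale=scale, quasi=quasi)
    l_spec = LagBasisSpec(max_lag=max_lag, df=lag_df)
    out: dict[str, tuple[FitResult, RRCurve]] = {}
    for name, mask in stratum_masks(counts.dates, scale).items():
        xs = exposure.values[mask]
        xs = xs[np.isfinite(xs)]
        n_params = exp_df * lag_df + model.n_time_knots + 1 + 7
        if mask.sum() < 5 * n_params or len(np.unique(xs)) <= exp_df:
            warnings.warn(f"stratum {name!r} too small ({int(mask.sum())} days); "
                          "skipped", stacklevel=2)
            continue
        e_spec = ExposureBasisSpec(exp_df).with_knots_from(xs)
        cb = build_cross_basis(exposure, e_spec, l_spec)
        try:
            fit = fit_count_regression(counts, cb, model, rows=mask)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"stratum {name!r} fit failed: {exc}", stacklevel=2)
            continue
        ref = float(np.median(xs))
        grid = np.linspace(xs.min(), xs.max(), grid_points)
        out[name] = (fit, predict_cumulative_rr(fit, cb, grid, ref))
    return out
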