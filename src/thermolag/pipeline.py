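"""End-to-end orchestration: simulate/load -> anomalies -> events -> DLNM."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anomaly import build_climatology, compute_anomalies, weekly_aggregate
from .dlnm import (ExposureBasisSpec, LagBasisSpec, ModelSpec, aic_grid_search,
                   build_cross_basis, fit_count_regression, predict_cumulative_rr)
from .events import (TempCategorySpec, classify_suicide_weeks,
                     classify_temperature_weeks, contingency, greatest_departure,
                     monthly_event_profile, select_months)
from .io import DailyBundle, read_daily_csv, write_daily_csv
from .simulate import SimConfig, preset, simulate_counts, simulate_temperature

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("thermolag")

MONTH_BY_NAME = {m: i + 1 for i, m in enumerate(
    ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"))}


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run.

    Either ``input_csv`` or a simulation ``preset`` must be given; every
    field is checked against the owning module's invariants before any
    computation starts.
    """

    input_csv: str | None = None
    preset: str | None = "toronto_like"
    absence_means_zero: bool = False
    smooth_halfwidth: int = 0
    low_q: float = 5.0
    high_q: float = 95.0
    months: list[int] | None = field(default_factory=lambda: [1, 7, 8, 9])
    n_months: int = 4
    cool_share: float = 0.14
    warm_share: float = 0.10
    variable: str = "greatest_departure"
    temp_var: str = "tmax"
    scale: str = "annual"
    max_lag: int = 6
    lag_df: int = 2
    temp_df: int = 4
    run_aic_grid: bool = False
    seed: int = 0
    outdir: str = "thermolag_out"

    def __post_init__(self) -> None:
        if self.input_csv is None and self.preset is None:
            raise ValueError("need either input_csv or a simulation preset")
        TempCategorySpec(self.cool_share, self.warm_share, self.variable)
        ExposureBasisSpec(self.temp_df)
        LagBasisSpec(self.max_lag, self.lag_df)
        ModelSpec(scale=self.scale)
        if not (0 <= self.low_q < self.high_q <= 100):
            raise ValueError("require 0 <= low_q < high_q <= 100")
        if self.temp_var not in ("tmax", "tmin"):
            raise ValueError("temp_var must be 'tmax' or 'tmin'")
        if self.months is not None:
            bad = [m for m in self.months if not 1 <= int(m) <= 12]
            if bad:
                raise ValueError(f"months out of range: {bad}")
            self.months = sorted(int(m) for m in self.months)
        if self.smooth_halfwidth < 0:
            raise ValueError("smooth_halfwidth must be >= 0")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of config keys")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_bundle(cfg: PipelineConfig) -> DailyBundle:
    if cfg.input_csv is not None:
        return read_daily_csv(cfg.input_csv, absence_means_zero=cfg.absence_means_zero)
    sim = preset(cfg.preset, seed=cfg.seed)
    tmax, tmin = simulate_temperature(sim)
    count = simulate_counts((tmax, tmin), sim)
    return DailyBundle(tmax, tmin, count)


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g", lineterminator="\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write all artifacts into ``cfg.outdir``.

    Deterministic for a fixed config (the seed drives the only randomness,
    the simulator).  Returns a dict of in-memory results keyed by stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load"
    try:
        bundle = _load_bundle(cfg)
        results["bundle"] = bundle
        write_daily_csv(bundle, out / "daily.csv")
        log.info("loaded %d days (%s .. %s)", len(bundle.dates),
                 bundle.dates[0].date(), bundle.dates[-1].date())

        stage = "climatology"
        clims = {name: build_climatology(series, cfg.smooth_halfwidth)
                 for name, series in (("count", bundle.count),
                                      ("tmax", bundle.tmax),
                                      ("tmin", bundle.tmin))}
        results["climatology"] = clims
        clim_df = pd.DataFrame({"doy": np.arange(1, 367)}
                               | {f"{k}_mean": v.doy_means for k, v in clims.items()}
                               | {f"{k}_n": v.counts_per_doy for k, v in clims.items()})
        _write_csv(clim_df, out / "climatology.csv")

        stage = "weekly_anomalies"
        weekly_count = weekly_aggregate(
            compute_anomalies(bundle.count, clims["count"]), "sum")
        weekly_tmax = weekly_aggregate(
            compute_anomalies(bundle.tmax, clims["tmax"]), "mean")
        weekly_tmin = weekly_aggregate(
            compute_anomalies(bundle.tmin, clims["tmin"]), "mean")
        results["weekly"] = {"count": weekly_count, "tmax": weekly_tmax,
                             "tmin": weekly_tmin}
        _write_csv(pd.DataFrame({
            "date": weekly_count.dates.strftime("%Y-%m-%d"),
            "count_sum": weekly_count.values,
            "tmax_mean": weekly_tmax.values,
            "tmin_mean": weekly_tmin.values}), out / "weekly_anomalies.csv")

        stage = "event_classification"
        labels, thresholds = classify_suicide_weeks(weekly_count, cfg.low_q, cfg.high_q)
        results["labels"], results["thresholds"] = labels, thresholds
        (out / "thresholds.json").write_text(json.dumps(
            {"low_cut": thresholds.low_cut, "high_cut": thresholds.high_cut,
             "low_q": thresholds.low_q, "high_q": thresholds.high_q}, indent=2) + "\n")

        stage = "monthly_profile"
        weekly_var = {"max": weekly_tmax, "min": weekly_tmin,
                      "greatest_departure": greatest_departure(weekly_tmax, weekly_tmin)
                      }[cfg.variable]
        profile = monthly_event_profile(weekly_var, labels)
        results["profile"] = profile
        _write_csv(profile.rename_axis("month"), out / "monthly_profile.csv", index=True)
        months = select_months(profile, cfg.n_months, override=cfg.months)
        results["months"] = months

        stage = "contingency"
        spec = TempCategorySpec(cfg.cool_share, cfg.warm_share, cfg.variable)
        temp_labels = classify_temperature_weeks(weekly_var, spec, months)
        table = contingency(labels, temp_labels)
        results["contingency"] = table
        _write_csv(table.counts.rename_axis("suicide"), out / "contingency_counts.csv",
                   index=True)
        _write_csv(table.col_pct.rename_axis("suicide"), out / "contingency_pct.csv",
                   index=True)

        stage = "dlnm"
        exposure = getattr(bundle, cfg.temp_var)
        e_spec = ExposureBasisSpec(cfg.temp_df).with_knots_from(exposure.values)
        cb = build_cross_basis(exposure, e_spec,
                               LagBasisSpec(cfg.max_lag, cfg.lag_df))
        fit = fit_count_regression(bundle.count, cb, ModelSpec(scale=cfg.scale))
        rr = predict_cumulative_rr(fit, cb)
        results["fit"], results["rr"] = fit, rr
        _write_csv(rr.to_frame(), out / f"rr_{cfg.temp_var}.csv")
        covered = float(np.mean(rr.covers_one()))
        results["null_check"] = covered
        log.info("RR CI covers 1 at %.0f%% of grid points", 100 * covered)

        if cfg.run_aic_grid:
            stage = "aic_grid"
            grid, best = aic_grid_search(bundle.count, exposure,
                                         model=ModelSpec(scale=cfg.scale))
            results["aic_grid"], results["aic_best"] = grid, best
            _write_csv(grid.reset_index(), out / "aic_grid.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage_log = {
        "thermolag_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": cfg.to_dict(),
        "selected_months": results["months"],
        "classified_days": results["contingency"].grand_total,
        "rr_ci_covers_one_share": results["null_check"],
    }
    (out / "run_log.txt").write_text(
        "\n".join(f"{k}: {json.dumps(v) if isinstance(v, (dict, list)) else v}"
                  for k, v in stage_log.items()) + "\n")
    return results
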