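import numpy as np
import pandas as pd
import pytest

from thermolag.anomaly import build_climatology, compute_anomalies, weekly_aggregate
from thermolag.series import DailySeries
from thermolag.simulate import preset, simulate_counts, simulate_temperature


@pytest.fixture(scope="session")
def toronto_small():
    """Six Toronto-like years with a fixed seed (shared across tests)."""
    cfg = preset("toronto_like", n_years=6, seed=42)
    tmax, tmin = simulate_temperature(cfg)
    count = simulate_counts((tmax, tmin), cfg)
    return {"config": cfg, "tmax": tmax, "tmin": tmin, "count": count}


@pytest.fixture(scope="session")
def toronto_weekly(toronto_small):
    """Weekly anomalies (count sum, tmax/tmin means) for the shared dataset."""
    out = {}
    for name, stat in (("count", "sum"), ("tmax", "mean"), ("tmin", "mean")):
        s = toronto_small[name]
        out[name] = weekly_aggregate(compute_anomalies(s, build_climatology(s)), stat)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_series(values, start="2000-01-01", kind="value", name=""):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries(dates, values, kind=kind, name=name)


@pytest.fixture()
def series_factory():
    return make_series
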