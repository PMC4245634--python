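import numpy as np
import pandas as pd
import pytest

from thermolag.anomaly import WeeklyAnomaly
from thermolag.events import (ContingencyTable, EventThresholds, TempCategorySpec,
                              classify_suicide_weeks, classify_temperature_weeks,
                              contingency, greatest_departure,
                              monthly_event_profile, select_months)

# Nine published day counts per temperature-variable block, used as fixed
# regression inputs (rows: high / normal / low; columns: cool / normal / warm).
BLOCK_COUNTS = {
    "min": [[3, 98, 18], [326, 2183, 222], [27, 69, 0]],
    "max": [[2, 102, 15], [255, 2300, 176], [22, 74, 0]],
    "greatest": [[3, 89, 27], [387, 2089, 255], [31, 65, 0]],
}
BLOCK_PCT = {
    "min": [[0.8, 4.2, 7.5], [91.6, 92.9, 92.5], [7.6, 2.9, 0.0]],
    "max": [[0.7, 4.1, 7.9], [91.4, 92.9, 92.1], [7.9, 3.0, 0.0]],
    "greatest": [[0.7, 4.0, 9.6], [91.9, 93.1, 90.4], [7.4, 2.9, 0.0]],
}


def _weekly(values, start="2000-01-01", stat="sum"):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return WeeklyAnomaly(dates, values, stat)


class TestClassifySuicideWeeks:
    def test_percentile_oracle_1_to_100(self):
        weekly = _weekly(np.arange(1.0, 101.0))
        labels, thr = classify_suicide_weeks(weekly)
        # brute-force check against a sort: percentile cuts are realized
        # values, labels use >= / <= inclusivity
        vals = np.arange(1.0, 101.0)
        assert thr.low_cut == pytest.approx(np.percentile(vals, 5))
        assert thr.high_cut == pytest.approx(np.percentile(vals, 95))
        assert (labels == "high").sum() == np.sum(vals >= thr.high_cut)
        assert (labels == "low").sum() == np.sum(vals <= thr.low_cut)
        assert (labels == "high").sum() == 5
        assert (labels == "low").sum() == 5

    def test_degenerate_all_equal_is_all_normal(self):
        labels, thr = classify_suicide_weeks(_weekly(np.full(60, 2.0)))
        assert thr.low_cut == thr.high_cut == 2.0
        assert (labels == "normal").all()

    def test_partition_of_eligible_days(self, toronto_weekly):
        weekly = toronto_weekly["count"]
        labels, _ = classify_suicide_weeks(weekly)
        eligible = np.isfinite(weekly.values)
        assert labels[eligible].isin(["high", "low", "normal"]).all()
        assert labels[~eligible].isna().all()

    def test_share_calibration_on_preset(self, toronto_weekly):
        labels, _ = classify_suicide_weeks(toronto_weekly["count"])
        n = labels.notna().sum()
        assert abs((labels == "high").sum() / n - 0.05) < 0.02
        assert abs((labels == "low").sum() / n - 0.05) < 0.02

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError, match="40"):
            classify_suicide_weeks(_weekly(np.arange(10.0)))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="eligible"):
            classify_suicide_weeks(_weekly(np.full(50, np.nan)))


class TestMonthlyProfile:
    def test_all_zero_anomalies(self):
        weekly = _weekly(np.zeros(400))
        labels = pd.Series("normal", index=weekly.dates)
        prof = monthly_event_profile(weekly, labels)
        assert np.allclose(prof["other"].dropna(), 0.0)

    def test_singleton_cell(self):
        weekly = _weekly(np.zeros(400), start="2000-01-01")
        vals = weekly.values.copy()
        july = np.where(weekly.dates.month == 7)[0][0]
        vals[july] = 2.5
        weekly = WeeklyAnomaly(weekly.dates, vals, "mean")
        labels = pd.Series("normal", index=weekly.dates, dtype=object)
        labels.iloc[july] = "high"
        prof = monthly_event_profile(weekly, labels)
        assert prof.loc[7, "high"] == pytest.approx(2.5)

    def test_brute_force_oracle(self, rng):
        weekly = _weekly(rng.normal(size=500))
        labels = pd.Series(rng.choice(["high", "low", "normal"], size=500),
                           index=weekly.dates)
        prof = monthly_event_profile(weekly, labels)
        for m in range(1, 13):
            for cls, lab in (("high", "high"), ("low", "low"), ("other", "normal")):
                sel = (weekly.dates.month == m) & (labels == lab).to_numpy()
                if sel.any():
                    assert prof.loc[m, cls] == pytest.approx(weekly.values[sel].mean())


class TestSelectMonths:
    def _profile(self, diffs):
        prof = pd.DataFrame({"high": diffs, "low": np.zeros(12),
                             "other": np.zeros(12)}, index=range(1, 13))
        return prof

    def test_constructed_ordering(self):
        prof = self._profile([5, 1, 1, 1, 1, 1, 4, 3, 2, 0, 0, 0])
        assert select_months(prof, 4) == [1, 7, 8, 9]

    def test_k_twelve_selects_all(self):
        prof = self._profile(np.arange(12.0))
        assert select_months(prof, 12) == list(range(1, 13))

    def test_override_wins(self):
        prof = self._profile(np.arange(12.0))
        assert select_months(prof, 4, override=[1, 7, 8, 9]) == [1, 7, 8, 9]

    def test_brute_force_ranking(self, rng):
        for _ in range(10):
            prof = pd.DataFrame({"high": rng.normal(size=12),
                                 "low": rng.normal(size=12),
                                 "other": np.zeros(12)}, index=range(1, 13))
            got = select_months(prof, 4)
            diff = (prof["high"] - prof["low"]).abs()
            expected = sorted(sorted(diff.index, key=lambda m: (-diff[m], m))[:4])
            assert got == expected

    def test_months_with_empty_cells_excluded(self):
        prof = self._profile(np.arange(12.0))
        prof.loc[12, "low"] = np.nan  # month with largest diff loses eligibility
        assert 12 not in select_months(prof, 4)


class TestGreatestDeparture:
    @pytest.mark.parametrize("mx,mn,expected", [
        (2.0, -1.0, 2.0),
        (-3.0, 2.0, -3.0),
        (-2.0, 2.0, -2.0),  # tie -> max-temperature variable, sign preserved
        (0.5, -4.0, -4.0),
    ])
    def test_cases(self, mx, mn, expected):
        wmax = _weekly([mx] * 7)
        wmin = _weekly([mn] * 7)
        out = greatest_departure(wmax, wmin)
        assert out.values[0] == pytest.approx(expected)

    def test_missing_propagates(self):
        out = greatest_departure(_weekly([np.nan, 1.0]), _weekly([2.0, 2.0]))
        assert np.isnan(out.values[0]) and out.values[1] == 2.0


class TestClassifyTemperatureWeeks:
    def test_share_oracle_1_to_100(self):
        weekly = _weekly(np.arange(1.0, 101.0))
        labels = classify_temperature_weeks(weekly, TempCategorySpec(0.14, 0.10))
        counts = labels.value_counts()
        assert counts["cool"] == 14
        assert counts["warm"] == 10
        assert counts["normal"] == 76
        # brute-force: the cool days are exactly the 14 smallest values
        assert set(np.where(labels == "cool")[0]) == set(range(14))
        assert set(np.where(labels == "warm")[0]) == set(range(90, 100))

    def test_symmetric_shares(self):
        weekly = _weekly(np.arange(-50.0, 50.0))
        labels = classify_temperature_weeks(weekly, TempCategorySpec(0.2, 0.2))
        assert (labels == "cool").sum() == (labels == "warm").sum()

    def test_restricted_to_selected_months(self, toronto_weekly):
        gd = greatest_departure(toronto_weekly["tmax"], toronto_weekly["tmin"])
        labels = classify_temperature_weeks(gd, TempCategorySpec(), [1, 7, 8, 9])
        outside = ~gd.dates.month.isin([1, 7, 8, 9])
        assert labels[outside].isna().all()
        n = labels.notna().sum()
        assert abs((labels == "cool").sum() / n - 0.14) < 0.02
        assert abs((labels == "warm").sum() / n - 0.10) < 0.02

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            TempCategorySpec(0.6, 0.5)
        with pytest.raises(ValueError):
            TempCategorySpec(0.0, 0.1)


class TestContingency:
    @pytest.mark.parametrize("block", sorted(BLOCK_COUNTS))
    def test_published_blocks_reproduced(self, block):
        table = ContingencyTable.from_counts(np.array(BLOCK_COUNTS[block]))
        assert np.allclose(table.col_pct.to_numpy(), np.array(BLOCK_PCT[block]))

    def test_greatest_block_shares(self):
        table = ContingencyTable.from_counts(np.array(BLOCK_COUNTS["greatest"]))
        assert table.grand_total == 2946
        shares = table.column_shares()
        assert round(100 * shares["cool"]) == 14
        assert round(100 * shares["warm"]) == 10

    def test_single_cell(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 0] = 17
        table = ContingencyTable.from_counts(counts)
        assert table.col_pct.iloc[0, 0] == 100.0
        assert np.isnan(table.col_pct.iloc[0, 1])  # empty column undefined

    def test_columns_sum_to_100(self):
        table = ContingencyTable.from_counts(np.array(BLOCK_COUNTS["greatest"]))
        sums = table.col_pct.sum(axis=0)
        assert np.all(np.abs(sums - 100.0) <= 0.2)

    def test_from_labels_matches_crosstab(self, rng):
        n = 300
        dates = pd.date_range("2000-01-01", periods=n, freq="D")
        s = pd.Series(rng.choice(["high", "normal", "low"], size=n), index=dates)
        t = pd.Series(rng.choice(["cool", "normal", "warm"], size=n), index=dates)
        s.iloc[:5] = None
        table = contingency(s, t)
        assert table.grand_total == s.notna().sum()
        for i, r in enumerate(["high", "normal", "low"]):
            for j, c in enumerate(["cool", "normal", "warm"]):
                manual = int(((s == r) & (t == c)).sum())
                assert table.counts.iloc[i, j] == manual

    def test_thresholds_invariant(self):
        with pytest.raises(ValueError):
            EventThresholds(low_cut=2.0, high_cut=1.0)
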