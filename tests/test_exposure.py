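"""Tests for time-of-day binning and exposure summaries."""

import numpy as np
import pandas as pd
import pytest

from heatdex import (
    DomainError,
    exceedance,
    incidence_by_bin,
    proportion_by_level,
    summarize_series,
    time_of_day_bin,
)
from heatdex.exposure import TIME_OF_DAY_BINS, assign_bins

from ._oracles import bin_of_hour, count_exceedance, count_incidence, count_proportions


class TestTimeOfDayBin:
    @pytest.mark.parametrize(
        "clock, expected",
        [
            ("06:00", "morning"), ("10:59", "morning"),
            ("11:00", "midday"), ("13:59", "midday"),
            ("14:00", "afternoon"), ("17:00", "afternoon"), ("17:59", "afternoon"),
            ("18:00", "night"), ("02:15", "night"), ("05:59", "night"),
        ],
    )
    def test_boundaries(self, clock, expected):
        assert time_of_day_bin(pd.Timestamp(f"2023-12-01T{clock}:00+02:00")) == expected

    def test_partition_of_every_minute(self):
        """The four bins partition the 1440 minutes of a day exactly."""
        minutes = pd.date_range(
            "2023-12-01T00:00+02:00", "2023-12-01T23:59+02:00", freq="1min"
        )
        bins = assign_bins(minutes)
        assert not bins.isna().any()
        counts = pd.Series(bins).value_counts()
        assert counts["morning"] == 5 * 60
        assert counts["midday"] == 3 * 60
        assert counts["afternoon"] == 4 * 60
        assert counts["night"] == 12 * 60
        for ts, b in zip(minutes, bins):
            assert b == bin_of_hour(ts.hour)

    def test_naive_timestamp_rejected(self):
        with pytest.raises(DomainError):
            time_of_day_bin(pd.Timestamp("2023-12-01T10:00:00"))


def _constant_series(n=96, temp=30.0, rh=50.0, start="2023-12-01T00:00+02:00"):
    idx = pd.date_range(start, periods=n, freq="15min")
    return pd.DataFrame({"air_temp_c": temp, "rel_humidity_pct": rh}, index=idx)


class TestSummarize:
    def test_constant_series(self, schemes):
        summary = summarize_series(_constant_series(), schemes)
        assert summary.n_readings == 96
        stats = summary.variables["air_temp_c"]
        assert stats.mean == 30.0 and stats.sd == 0.0
        props = summary.level_proportions["humidex_1"]
        assert (props > 0).sum() == 1 and props.max() == 100.0

    def test_hand_computed_mean_and_sd(self, schemes):
        temps = [28.1, 29.4, 30.2, 27.6, 31.8, 33.0, 29.9, 26.5, 32.4, 30.7]
        series = _constant_series(n=10)
        series["air_temp_c"] = temps
        summary = summarize_series(series, schemes)
        # spreadsheet-style hand computation, independent of pandas
        assert summary.variables["air_temp_c"].mean == pytest.approx(29.96, abs=1e-9)
        assert summary.variables["air_temp_c"].sd == pytest.approx(2.121425097533364, abs=1e-9)

    def test_ties_for_max_report_all_timestamps(self, schemes):
        series = _constant_series(n=8, temp=28.0)
        series.iloc[2, 0] = 33.92
        series.iloc[3, 0] = 33.92
        stats = summarize_series(series, schemes).variables["air_temp_c"]
        assert stats.max == 33.92
        assert stats.argmax == (series.index[2], series.index[3])

    def test_order_permutation_invariance(self, schemes):
        rng = np.random.default_rng(3)
        series = _constant_series(n=50)
        series["air_temp_c"] = rng.uniform(22, 34, 50)
        shuffled = series.sample(frac=1.0, random_state=1)
        a = summarize_series(series, schemes).variables["air_temp_c"]
        b = summarize_series(shuffled, schemes).variables["air_temp_c"]
        assert a.mean == pytest.approx(b.mean, rel=1e-12)
        assert a.sd == pytest.approx(b.sd, rel=1e-12)

    def test_empty_series_rejected(self, schemes):
        with pytest.raises(DomainError):
            summarize_series(_constant_series(n=96).iloc[:0], schemes)

    def test_proportions_sum_to_100(self, schemes, study_series):
        summary = summarize_series(study_series, schemes)
        for props in summary.level_proportions.values():
            assert props.sum() == pytest.approx(100.0, abs=0.1)
        assert summary.bin_counts.sum() == summary.n_readings


class TestCountingStatistics:
    def test_constructed_quarter_split(self, schemes):
        scheme = schemes["humidex_1"]
        # values placed in the middle of four consecutive bands
        values = np.repeat([25.0, 31.0, 35.0, 39.0], 25)
        props = proportion_by_level(scheme.classify(values), scheme)
        assert props.loc[[0, 1, 2, 3]].tolist() == [25.0, 25.0, 25.0, 25.0]
        assert props.loc[[4, 5, 6, 7]].tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_single_reading(self, schemes):
        scheme = schemes["humidex_2"]
        props = proportion_by_level([3], scheme)
        assert props.loc[3] == 100.0 and props.sum() == 100.0

    def test_exceedance_degenerate_cases(self, schemes):
        scheme = schemes["humidex_2"]
        assert exceedance([0] * 10, scheme, 1) == 0.0
        assert exceedance([7] * 10, scheme, 4) == 100.0
        with pytest.raises(KeyError):
            exceedance([0], scheme, 99)

    def test_brute_force_equivalence(self, schemes):
        scheme = schemes["humidex_2"]
        rng = np.random.default_rng(11)
        idx = pd.date_range("2023-12-01T00:00+02:00", periods=400, freq="37min")
        levels = rng.integers(0, 8, len(idx))
        props = proportion_by_level(levels, scheme)
        expected = count_proportions(levels, scheme.levels)
        for lv in scheme.levels:
            assert props.loc[lv] == pytest.approx(expected[lv])
        assert exceedance(levels, scheme, 4) == pytest.approx(count_exceedance(levels, 4))
        table = incidence_by_bin(idx, levels, scheme)
        expected_table = count_incidence(idx, levels, scheme.levels)
        for b in TIME_OF_DAY_BINS:
            for lv in scheme.levels:
                assert table.counts.loc[b, lv] == expected_table[b][lv]

    def test_incidence_row_sums_and_empty_bin(self, schemes):
        scheme = schemes["humidex_2"]
        # readings only at night: all other bins are zero rows, no errors
        idx = pd.date_range("2023-12-01T19:00+02:00", periods=10, freq="15min")
        table = incidence_by_bin(idx, [0] * 10, scheme)
        assert table.counts.loc["night"].sum() == 10
        assert table.counts.loc[["morning", "midday", "afternoon"]].to_numpy().sum() == 0

    def test_uniform_day_bin_widths(self, schemes):
        """Equally spaced 24-h readings fall into bins proportionally to
        bin width (5/3/4/12 hours)."""
        scheme = schemes["humidex_1"]
        idx = pd.date_range("2023-12-01T00:00+02:00", periods=96, freq="15min")
        table = incidence_by_bin(idx, [1] * 96, scheme)
        assert table.bin_totals.tolist() == [20, 12, 16, 48]

    def test_night_only_no_risk_fixture(self, schemes):
        """A series whose only sub-threshold readings occur at night mirrors
        the qualitative pattern that no-risk incidence is nocturnal."""
        scheme = schemes["humidex_2"]
        night = pd.date_range("2023-12-01T22:00+02:00", periods=20, freq="15min")
        day = pd.date_range("2023-12-02T12:00+02:00", periods=20, freq="15min")
        idx = night.append(day)
        values = np.array([24.0] * 20 + [36.5] * 20)  # below level 1 vs level 4
        table = incidence_by_bin(idx, scheme.classify(values), scheme)
        zero_risk = table.counts[0]
        assert zero_risk.loc["night"] == 20
        assert zero_risk.drop("night").sum() == 0
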