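"""Tests for shift decomposition and the work/exposure overlay."""

import numpy as np
import pandas as pd
import pytest

from heatdex import DomainError, Shift, exposure_during_work, hours_per_bin, read_roster_csv
from heatdex.exposure import TIME_OF_DAY_BINS
from heatdex.roster import on_duty_mask

from ._oracles import roster_hours_by_minute


def _shift(role, start, end):
    return Shift(role=role, start=pd.Timestamp(start), end=pd.Timestamp(end))


class TestHoursPerBin:
    def test_night_shift_splits_at_morning_boundary(self):
        summary = hours_per_bin(
            [_shift("ED", "2023-12-01T18:00+02:00", "2023-12-02T08:00+02:00")]
        )
        row = summary.hours.loc["ED"]
        assert row["night"] == pytest.approx(12.0)
        assert row["morning"] == pytest.approx(2.0)
        assert row["midday"] == 0.0 and row["afternoon"] == 0.0

    def test_morning_shift_splits_at_midday(self):
        summary = hours_per_bin(
            [_shift("ward", "2023-12-01T09:00+02:00", "2023-12-01T12:00+02:00")]
        )
        row = summary.hours.loc["ward"]
        assert row["morning"] == pytest.approx(2.0)
        assert row["midday"] == pytest.approx(1.0)

    def test_month_of_random_shifts_matches_minute_accumulation(self):
        rng = np.random.default_rng(5)
        shifts = []
        t = pd.Timestamp("2023-12-01T07:00+02:00")
        for day in range(28):
            start = t + pd.Timedelta(days=day, minutes=int(rng.integers(0, 720)))
            duration = int(rng.integers(4 * 60, 14 * 60))
            role = "ED" if day % 2 == 0 else "ward"
            shifts.append(_shift(role, start, start + pd.Timedelta(minutes=duration)))
        summary = hours_per_bin(shifts)
        expected = roster_hours_by_minute(shifts)
        for role, bins in expected.items():
            for b in TIME_OF_DAY_BINS:
                assert summary.hours.loc[role, b] == pytest.approx(bins[b], abs=1e-9)

    def test_hour_conservation(self):
        shifts = [
            _shift("ED", "2023-12-01T16:30+02:00", "2023-12-02T02:15+02:00"),
            _shift("ED", "2023-12-02T08:00+02:00", "2023-12-02T17:00+02:00"),
        ]
        summary = hours_per_bin(shifts)
        total = sum(s.duration_hours for s in shifts)
        assert summary.totals["ED"] == pytest.approx(total, abs=1e-6)

    def test_overlapping_shifts_rejected(self):
        with pytest.raises(DomainError, match="overlap"):
            hours_per_bin(
                [
                    _shift("ED", "2023-12-01T08:00+02:00", "2023-12-01T18:00+02:00"),
                    _shift("ED", "2023-12-01T16:00+02:00", "2023-12-01T22:00+02:00"),
                ]
            )

    def test_different_roles_may_overlap(self):
        summary = hours_per_bin(
            [
                _shift("ED", "2023-12-01T08:00+02:00", "2023-12-01T18:00+02:00"),
                _shift("ward", "2023-12-01T08:00+02:00", "2023-12-01T18:00+02:00"),
            ]
        )
        assert summary.totals.tolist() == [10.0, 10.0]


class TestShiftValidation:
    def test_end_before_start_rejected(self):
        with pytest.raises(DomainError):
            _shift("ED", "2023-12-01T18:00+02:00", "2023-12-01T08:00+02:00")

    def test_marathon_shift_rejected(self):
        with pytest.raises(DomainError, match="36"):
            _shift("ED", "2023-12-01T08:00+02:00", "2023-12-03T08:00+02:00")

    def test_naive_timestamps_rejected(self):
        with pytest.raises(DomainError):
            Shift("ED", pd.Timestamp("2023-12-01T08:00"), pd.Timestamp("2023-12-01T18:00"))


class TestWorkExposure:
    def _series(self):
        idx = pd.date_range("2023-12-01T00:00+02:00", periods=96, freq="15min")
        # hot around midday, cool at night
        levels = np.where((idx.hour >= 11) & (idx.hour < 18), 4, 1)
        return idx, levels

    def test_full_coverage_equals_total(self, schemes):
        idx, levels = self._series()
        shifts = [
            _shift("ED", "2023-11-30T23:00+02:00", "2023-12-01T23:00+02:00"),
            _shift("ED", "2023-12-01T23:00+02:00", "2023-12-02T03:00+02:00"),
        ]
        we = exposure_during_work(shifts, idx, levels, schemes["humidex_2"])
        assert we.n_off_duty == 0 and we.off_duty is None
        assert we.on_duty.counts.to_numpy().sum() == len(idx)

    def test_no_shifts_everything_off_duty(self, schemes):
        idx, levels = self._series()
        we = exposure_during_work([], idx, levels, schemes["humidex_2"])
        assert we.n_on_duty == 0 and we.on_duty is None
        assert we.off_duty.counts.to_numpy().sum() == len(idx)

    def test_night_roster_leaves_hot_midday_off_duty(self, schemes):
        """Brute-force membership check: with night shifts only, all
        high-level (midday) readings fall off duty."""
        idx, levels = self._series()
        shifts = [_shift("ED", "2023-12-01T19:00+02:00", "2023-12-02T06:00+02:00")]
        we = exposure_during_work(shifts, idx, levels, schemes["humidex_2"])
        expected_mask = np.array(
            [shifts[0].start <= t < shifts[0].end for t in idx], dtype=bool
        )
        assert np.array_equal(on_duty_mask(idx, shifts), expected_mask)
        assert we.n_on_duty + we.n_off_duty == len(idx)
        assert we.off_duty.counts[4].sum() == (levels == 4).sum()
        assert we.on_duty.counts[4].sum() == 0

    def test_membership_is_start_inclusive_end_exclusive(self):
        idx = pd.DatetimeIndex(
            [pd.Timestamp("2023-12-01T08:00+02:00"), pd.Timestamp("2023-12-01T18:00+02:00")]
        )
        mask = on_duty_mask(idx, [_shift("ED", "2023-12-01T08:00+02:00", "2023-12-01T18:00+02:00")])
        assert mask.tolist() == [True, False]


class TestRosterCsv:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "roster.csv"
        path.write_text(
            "role,start,end\n"
            "ED,2023-12-01T18:00:00+02:00,2023-12-02T08:00:00+02:00\n"
            "ward,2023-12-01T08:00:00+02:00,2023-12-01T17:00:00+02:00\n"
        )
        shifts = read_roster_csv(path)
        assert [s.role for s in shifts] == ["ED", "ward"]
        assert shifts[0].duration_hours == 14.0

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "roster.csv"
        path.write_text("role,start\nED,2023-12-01T18:00:00+02:00\n")
        with pytest.raises(Exception, match="missing"):
            read_roster_csv(path)

    def test_naive_roster_times_rejected(self, tmp_path):
        path = tmp_path / "roster.csv"
        path.write_text("role,start,end\nED,2023-12-01T18:00,2023-12-02T08:00\n")
        with pytest.raises(Exception, match="offset"):
            read_roster_csv(path)
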