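"""Duty-roster overlay: decompose shifts into time-of-day bin hours and
restrict heat-stress incidence to on-duty (or off-duty) periods.

Shifts are half-open intervals ``[start, end)`` so consecutive shifts
compose without double counting.  A shift crossing a bin boundary
(including midnight) is split exactly at every boundary it crosses and its
duration apportioned to the bins of the resulting segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import ClassificationScheme
from .errors import DomainError, LoggerFormatError
from .exposure import TIME_OF_DAY_BINS, BinLevelTable, incidence_by_bin, time_of_day_bin

__all__ = [
    "Shift",
    "RosterSummary",
    "hours_per_bin",
    "exposure_during_work",
    "read_roster_csv",
]

MAX_SHIFT_HOURS = 36.0

# Local clock hours at which a new time-of-day bin begins.
_BIN_START_HOURS = (6, 11, 14, 18)


@dataclass(frozen=True)
class Shift:
    """One duty interval for one role (e.g. ``"ED"`` or ``"ward"``)."""

    role: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self):
        start, end = pd.Timestamp(self.start), pd.Timestamp(self.end)
        if start.tzinfo is None or end.tzinfo is None:
            raise DomainError(f"shift {self.role!r}: start/end lack a UTC offset")
        if not end > start:
            raise DomainError(
                f"shift {self.role!r}: end {end.isoformat()} not after "
                f"start {start.isoformat()}"
            )
        if (end - start) > pd.Timedelta(hours=MAX_SHIFT_HOURS):
            raise DomainError(
                f"shift {self.role!r}: duration exceeds {MAX_SHIFT_HOURS} h sanity gate"
            )
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)

    @property
    def duration_hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


@dataclass(frozen=True)
class RosterSummary:
    """Hours per time-of-day bin per role.

    ``hours`` is a role x bin DataFrame; per-role bin hours sum to that
    role's total shift hours (exact apportioning, tolerance 1e-6).
    """

    hours: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.hours.sum(axis=1)

    def to_dict(self) -> dict:
        return {
            role: {b: float(h) for b, h in row.items()}
            for role, row in self.hours.iterrows()
        }


def _check_no_overlap(shifts: Sequence[Shift]) -> None:
    by_role: dict[str, list[Shift]] = {}
    for s in shifts:
        by_role.setdefault(s.role, []).append(s)
    for role, items in by_role.items():
        items.sort(key=lambda s: s.start)
        for prev, nxt in zip(items, items[1:]):
            if nxt.start < prev.end:
                raise DomainError(
                    f"overlapping shifts for role {role!r}: "
                    f"{prev.start.isoformat()}–{prev.end.isoformat()} and "
                    f"{nxt.start.isoformat()}–{nxt.end.isoformat()}"
                )


def _bin_boundaries_between(start: pd.Timestamp, end: pd.Timestamp) -> list[pd.Timestamp]:
    """All bin-start instants strictly inside (start, end)."""
    cuts = []
    day = start.normalize()
    while day <= end.normalize():
        for hour in _BIN_START_HOURS:
            t = day + pd.Timedelta(hours=hour)
            if start < t < end:
                cuts.append(t)
        day += pd.Timedelta(days=1)
    return cuts


def hours_per_bin(shifts: Iterable[Shift]) -> RosterSummary:
    """Apportion shift durations to time-of-day bins, per role.

    Each shift is split at every bin boundary it crosses; each segment's
    duration is credited to the bin its start instant falls in.  Hour
    conservation (bin hours sum to shift hours) is exact by construction.
    """
    shifts = list(shifts)
    _check_no_overlap(shifts)
    roles = sorted({s.role for s in shifts})
    hours = pd.DataFrame(0.0, index=roles, columns=list(TIME_OF_DAY_BINS))
    hours.index.name = "role"
    for shift in shifts:
        edges = [shift.start, *_bin_boundaries_between(shift.start, shift.end), shift.end]
        for seg_start, seg_end in zip(edges, edges[1:]):
            b = time_of_day_bin(seg_start)
            hours.loc[shift.role, b] += (seg_end - seg_start) / pd.Timedelta(hours=1)
    return RosterSummary(hours=hours)


def on_duty_mask(timestamps: pd.DatetimeIndex, shifts: Iterable[Shift]) -> np.ndarray:
    """Boolean mask of readings falling inside any shift (start-inclusive,
    end-exclusive)."""
    ts = pd.DatetimeIndex(timestamps)
    if ts.tz is None:
        raise DomainError("series timestamps lack a UTC offset")
    mask = np.zeros(len(ts), dtype=bool)
    for s in shifts:
        mask |= (ts >= s.start) & (ts < s.end)
    return mask


@dataclass(frozen=True)
class WorkExposure:
    """Incidence tables restricted to on-duty and off-duty readings."""

    on_duty: BinLevelTable | None
    off_duty: BinLevelTable | None
    n_on_duty: int
    n_off_duty: int


def exposure_during_work(
    shifts: Iterable[Shift],
    timestamps: pd.DatetimeIndex,
    levels,
    scheme: ClassificationScheme,
) -> WorkExposure:
    """Split bin x level incidence into on-duty and off-duty components.

    Readings are labelled on-duty by half-open interval membership; the two
    tables partition the series (counts sum to the full table).  An empty
    side yields ``None`` rather than a degenerate table.
    """
    shifts = list(shifts)
    ts = pd.DatetimeIndex(timestamps)
    arr = np.asarray(levels, dtype=int)
    if len(ts) != arr.size:
        raise DomainError("timestamps and levels differ in length")
    mask = on_duty_mask(ts, shifts)
    on = incidence_by_bin(ts[mask], arr[mask], scheme) if mask.any() else None
    off = incidence_by_bin(ts[~mask], arr[~mask], scheme) if (~mask).any() else None
    return WorkExposure(
        on_duty=on, off_duty=off, n_on_duty=int(mask.sum()), n_off_duty=int((~mask).sum())
    )


def read_roster_csv(path: str | Path) -> list[Shift]:
    """Read shifts from CSV with columns ``role,start,end`` (ISO-8601 with
    UTC offset)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise LoggerFormatError(f"unparseable roster file {path}: {exc}") from exc
    missing = {"role", "start", "end"} - set(df.columns)
    if missing:
        raise LoggerFormatError(f"roster file {path} missing columns {sorted(missing)}")
    shifts = []
    for i, row in df.iterrows():
        start = pd.Timestamp(row["start"])
        end = pd.Timestamp(row["end"])
        if start.tzinfo is None or end.tzinfo is None:
            raise LoggerFormatError(f"roster row {i + 2}: timestamp lacks a UTC offset")
        shifts.append(Shift(role=str(row["role"]), start=start, end=end))
    _check_no_overlap(shifts)
    return shifts
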