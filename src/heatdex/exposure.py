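"""Exposure summaries: distribution statistics, per-level proportions,
time-of-day incidence and level exceedance.

The day is partitioned into four local-clock bins — morning 06:00-10:59,
midday 11:00-13:59, afternoon 14:00-17:59 and night 18:00-05:59 (spanning
midnight).  Incidence is attributed to the calendar time of each reading.
Summary statistics use the sample (n-1) standard deviation, and extrema
report *all* tied timestamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classification import ClassificationScheme
from .errors import DomainError
from .indices import heat_index, humidex

__all__ = [
    "TIME_OF_DAY_BINS",
    "time_of_day_bin",
    "assign_bins",
    "proportion_by_level",
    "exceedance",
    "incidence_by_bin",
    "summarize_series",
    "BinLevelTable",
    "VariableStats",
    "ExposureSummary",
]

TIME_OF_DAY_BINS = ("morning", "midday", "afternoon", "night")

# Bin of each local clock hour 0..23.
_HOUR_TO_BIN = np.array(
    ["night"] * 6 + ["morning"] * 5 + ["midday"] * 3 + ["afternoon"] * 4 + ["night"] * 6
)


def time_of_day_bin(timestamp) -> str:
    """Time-of-day bin of a single timezone-aware instant.

    Raises
    ------
    DomainError
        If the timestamp carries no UTC offset (local clock ambiguity is
        never guessed).
    """
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        raise DomainError(f"timestamp={ts.isoformat()} lacks a UTC offset")
    return str(_HOUR_TO_BIN[ts.hour])


def assign_bins(index: pd.DatetimeIndex) -> pd.Categorical:
    """Vectorised bin assignment for a timezone-aware DatetimeIndex."""
    if index.tz is None:
        raise DomainError("series timestamps lack a UTC offset")
    return pd.Categorical(
        _HOUR_TO_BIN[index.hour], categories=list(TIME_OF_DAY_BINS), ordered=True
    )


def _levels_array(levels) -> np.ndarray:
    arr = np.asarray(levels, dtype=int)
    if arr.size == 0:
        raise DomainError("empty classified series")
    return arr


def proportion_by_level(levels, scheme: ClassificationScheme) -> pd.Series:
    """Percentage of readings at each scheme level (absent levels are 0)."""
    arr = _levels_array(levels)
    counts = pd.Series(arr).value_counts()
    out = pd.Series(0.0, index=list(scheme.levels), name=scheme.name)
    for level, count in counts.items():
        out.loc[int(level)] = 100.0 * count / arr.size
    out.index.name = "level"
    return out


def exceedance(levels, scheme: ClassificationScheme, level: int) -> float:
    """Percentage of readings at or above ``level`` under ``scheme``."""
    arr = _levels_array(levels)
    if int(level) not in scheme.levels:
        raise KeyError(f"scheme {scheme.name!r} has no level {level}")
    return float(100.0 * np.mean(arr >= int(level)))


@dataclass(frozen=True)
class BinLevelTable:
    """Time-of-day x level contingency table (counts and % of all readings)."""

    counts: pd.DataFrame
    proportions: pd.DataFrame

    @property
    def bin_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def incidence_by_bin(
    timestamps: pd.DatetimeIndex, levels, scheme: ClassificationScheme
) -> BinLevelTable:
    """Cross-tabulate heat-stress level against time-of-day bin.

    Rows are the four bins (all present, zero-filled), columns the scheme's
    levels; row sums equal per-bin reading counts.
    """
    arr = _levels_array(levels)
    if len(timestamps) != arr.size:
        raise DomainError("timestamps and levels differ in length")
    bins = assign_bins(pd.DatetimeIndex(timestamps))
    counts = (
        pd.crosstab(bins, pd.Series(arr, name="level"), dropna=False)
        .reindex(index=list(TIME_OF_DAY_BINS), columns=list(scheme.levels), fill_value=0)
        .astype(int)
    )
    counts.index.name = "time_of_day"
    return BinLevelTable(counts=counts, proportions=100.0 * counts / arr.size)


@dataclass(frozen=True)
class VariableStats:
    """Distributional summary of one variable with extremum timestamps."""

    mean: float
    sd: float
    min: float
    max: float
    argmin: tuple[pd.Timestamp, ...]
    argmax: tuple[pd.Timestamp, ...]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "argmin": [ts.isoformat() for ts in self.argmin],
            "argmax": [ts.isoformat() for ts in self.argmax],
        }


@dataclass(frozen=True)
class ExposureSummary:
    """Full exposure report for one reading series."""

    n_readings: int
    n_excluded: int
    variables: Mapping[str, VariableStats]
    level_proportions: Mapping[str, pd.Series]
    incidence: Mapping[str, BinLevelTable]
    bin_counts: pd.Series = field(default=None)

    def to_dict(self) -> dict:
        return {
            "n_readings": self.n_readings,
            "n_excluded": self.n_excluded,
            "variables": {k: v.to_dict() for k, v in self.variables.items()},
            "level_proportions": {
                k: {int(level): float(p) for level, p in s.items()}
                for k, s in self.level_proportions.items()
            },
            "incidence_counts": {
                k: {
                    b: {int(level): int(c) for level, c in row.items()}
                    for b, row in t.counts.iterrows()
                }
                for k, t in self.incidence.items()
            },
            "bin_counts": {b: int(c) for b, c in self.bin_counts.items()},
        }


def _variable_stats(values: pd.Series) -> VariableStats:
    v = values.astype(float)
    vmin, vmax = float(v.min()), float(v.max())
    return VariableStats(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        min=vmin,
        max=vmax,
        argmin=tuple(v.index[v == vmin]),
        argmax=tuple(v.index[v == vmax]),
    )


def summarize_series(
    series: pd.DataFrame,
    schemes: Mapping[str, ClassificationScheme],
    *,
    n_excluded: int = 0,
) -> ExposureSummary:
    """Summarise a reading series under a set of classification schemes.

    Parameters
    ----------
    series : DataFrame
        Timezone-aware DatetimeIndex; columns ``air_temp_c`` and
        ``rel_humidity_pct``.  Index columns (``humidex_c``,
        ``heat_index_c``/``heat_index_f``) are computed if absent.
    schemes : mapping
        Scheme name -> :class:`ClassificationScheme`; each scheme is applied
        to the index column it declares.
    n_excluded : int
        Readings dropped upstream (reported, never imputed).

    Raises
    ------
    DomainError
        On an empty series or timestamps without a UTC offset.
    """
    if len(series) == 0:
        raise DomainError("empty reading series")
    if series.index.tz is None:
        raise DomainError("series timestamps lack a UTC offset")
    df = series.copy()
    if "humidex_c" not in df:
        df["humidex_c"] = humidex(df["air_temp_c"].to_numpy(), df["rel_humidity_pct"].to_numpy())
    needs_hi = any(s.index == "heat_index_c" for s in schemes.values())
    if needs_hi and "heat_index_c" not in df:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # indoor series routinely dip below 80 degF
            hi_f, hi_c = heat_index(
                df["air_temp_c"].to_numpy(), df["rel_humidity_pct"].to_numpy()
            )
        df["heat_index_f"], df["heat_index_c"] = hi_f, hi_c

    variables = {
        name: _variable_stats(df[name])
        for name in ("air_temp_c", "rel_humidity_pct", "humidex_c")
        if name in df
    }
    level_proportions: dict[str, pd.Series] = {}
    incidence: dict[str, BinLevelTable] = {}
    for name, scheme in schemes.items():
        levels = scheme.classify(df[scheme.index].to_numpy())
        level_proportions[name] = proportion_by_level(levels, scheme)
        incidence[name] = incidence_by_bin(df.index, levels, scheme)
    bin_counts = (
        pd.Series(assign_bins(df.index)).value_counts().reindex(list(TIME_OF_DAY_BINS), fill_value=0)
    )
    bin_counts.index.name = "time_of_day"
    return ExposureSummary(
        n_readings=len(df),
        n_excluded=n_excluded,
        variables=variables,
        level_proportions=level_proportions,
        incidence=incidence,
        bin_counts=bin_counts,
    )
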