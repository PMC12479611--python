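"""Independent oracles used only by the test suite.

These deliberately avoid the package's own code paths: the Rothfusz 9-term
regression is a different published fit of the same apparent-temperature
surface, and the counting oracles are naive loops.
"""

from __future__ import annotations

import pandas as pd


def rothfusz_heat_index_f(t_f: float, rh: float) -> float:
    """NWS Rothfusz 9-term regression (deg F), the independent cross-check
    for the 16-term full polynomial."""
    T, R = t_f, rh
    return (
        -42.379
        + 2.04901523 * T
        + 10.14333127 * R
        - 0.22475541 * T * R
        - 6.83783e-3 * T * T
        - 5.481717e-2 * R * R
        + 1.22874e-3 * T * T * R
        + 8.5282e-4 * T * R * R
        - 1.99e-6 * T * T * R * R
    )


def bin_of_hour(hour: int) -> str:
    if 6 <= hour <= 10:
        return "morning"
    if 11 <= hour <= 13:
        return "midday"
    if 14 <= hour <= 17:
        return "afternoon"
    return "night"


def count_proportions(levels, scheme_levels) -> dict[int, float]:
    out = {lv: 0 for lv in scheme_levels}
    for lv in levels:
        out[int(lv)] += 1
    n = len(levels)
    return {lv: 100.0 * c / n for lv, c in out.items()}


def count_exceedance(levels, threshold: int) -> float:
    hits = sum(1 for lv in levels if int(lv) >= threshold)
    return 100.0 * hits / len(levels)


def count_incidence(timestamps, levels, scheme_levels) -> dict[str, dict[int, int]]:
    table = {
        b: {lv: 0 for lv in scheme_levels}
        for b in ("morning", "midday", "afternoon", "night")
    }
    for ts, lv in zip(timestamps, levels):
        table[bin_of_hour(pd.Timestamp(ts).hour)][int(lv)] += 1
    return table


def roster_hours_by_minute(shifts) -> dict[str, dict[str, float]]:
    """Minute-resolution accumulation of shift hours into time-of-day bins.

    Valid for shifts whose start/end fall on whole minutes.
    """
    out: dict[str, dict[str, float]] = {}
    for shift in shifts:
        acc = out.setdefault(
            shift.role, {b: 0.0 for b in ("morning", "midday", "afternoon", "night")}
        )
        t = pd.Timestamp(shift.start)
        while t < shift.end:
            acc[bin_of_hour(t.hour)] += 1.0 / 60.0
            t += pd.Timedelta(minutes=1)
    return out
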