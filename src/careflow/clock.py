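"""Model-time calendar.

Simulation time is measured in minutes from t = 0, which represents
00:00 on 1 January of a non-leap year.  The weekday of day 0 is
configurable (default Friday, matching a 2021-style calendar year).
Arrival rates are stratified by (hour of day, calendar quarter,
weekend flag): 24 x 4 x 2 = 192 strata.
"""

from __future__ import annotations

from bisect import bisect_right

MINUTES_PER_HOUR = 60
MINUTES_PER_DAY = 1440
DAYS_PER_YEAR = 365
MINUTES_PER_YEAR = DAYS_PER_YEAR * MINUTES_PER_DAY

#: Cumulative last-day-of-quarter for a non-leap year (Q1 = Jan-Mar = 90 days).
_QUARTER_CUM_DAYS = (90, 181, 273)

WEEKDAY_NAMES = (
    "monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday",
)
#: Day 0 defaults to a Friday (1 January 2021 was a Friday).
DEFAULT_START_WEEKDAY = 4

N_STRATA = 24 * 4 * 2

Stratum = tuple  # (hour: int, quarter: int, is_weekend: bool)


def hour_of(t: float) -> int:
    return int(t // MINUTES_PER_HOUR) % 24


def day_of(t: float) -> int:
    return int(t // MINUTES_PER_DAY)


def weekday_of(t: float, start_weekday: int = DEFAULT_START_WEEKDAY) -> int:
    """Weekday index of model time ``t`` (0 = Monday ... 6 = Sunday)."""
    return (start_weekday + day_of(t)) % 7


def is_weekend(t: float, start_weekday: int = DEFAULT_START_WEEKDAY) -> bool:
    return weekday_of(t, start_weekday) >= 5


def quarter_of(t: float) -> int:
    """Calendar quarter (1-4) of model time ``t``; years beyond the first wrap."""
    day_in_year = day_of(t) % DAYS_PER_YEAR
    return 1 + bisect_right(_QUARTER_CUM_DAYS, day_in_year)


def stratum_of(t: float, start_weekday: int = DEFAULT_START_WEEKDAY) -> Stratum:
    return (hour_of(t), quarter_of(t), is_weekend(t, start_weekday))


def next_hour_boundary(t: float) -> float:
    return (int(t // MINUTES_PER_HOUR) + 1) * float(MINUTES_PER_HOUR)


def all_strata() -> list[Stratum]:
    """The complete, ordered list of 192 arrival strata."""
    return [
        (hour, quarter, weekend)
        for hour in range(24)
        for quarter in (1, 2, 3, 4)
        for weekend in (False, True)
    ]


def stratum_exposure_minutes(
    span_minutes: float, start_weekday: int = DEFAULT_START_WEEKDAY
) -> dict[Stratum, float]:
    """Minutes each stratum is "live" over the window [0, span_minutes).

    Walks hour blocks, so a partial final hour is pro-rated.
    """
    exposure: dict[Stratum, float] = {s: 0.0 for s in all_strata()}
    n_hours = int(-(-span_minutes // MINUTES_PER_HOUR))  # ceil
    for k in range(n_hours):
        t = k * MINUTES_PER_HOUR
        exposure[stratum_of(t, start_weekday)] += min(
            float(MINUTES_PER_HOUR), span_minutes - t
        )
    return exposure


def parse_weekday(name) -> int:
    """Accept a weekday name (case-insensitive) or an integer 0-6."""
    if isinstance(name, int):
        if not 0 <= name <= 6:
            raise ValueError(f"weekday index out of range: {name}")
        return name
    try:
        return WEEKDAY_NAMES.index(str(name).strip().lower())
    except ValueError:
        raise ValueError(f"unknown weekday name: {name!r}") from None
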