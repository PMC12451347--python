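"""Ramadan calendar configuration.

Window construction needs only the Gregorian start and end dates of Ramadan
per calendar year; these are configuration, not computed (no Hijri
conversion).  A default 2013-2019 calendar is bundled; any mapping
``year -> (start, end)`` loaded from YAML can replace it.
"""

from __future__ import annotations

import datetime as dt

import yaml

#: Gregorian Ramadan dates (first and last day of fasting) used by default.
DEFAULT_RAMADAN_CALENDAR: dict[int, tuple[dt.date, dt.date]] = {
    2013: (dt.date(2013, 7, 9), dt.date(2013, 8, 7)),
    2014: (dt.date(2014, 6, 28), dt.date(2014, 7, 27)),
    2015: (dt.date(2015, 6, 18), dt.date(2015, 7, 16)),
    2016: (dt.date(2016, 6, 6), dt.date(2016, 7, 5)),
    2017: (dt.date(2017, 5, 27), dt.date(2017, 6, 24)),
    2018: (dt.date(2018, 5, 16), dt.date(2018, 6, 14)),
    2019: (dt.date(2019, 5, 6), dt.date(2019, 6, 3)),
}


def validate_calendar(calendar: dict[int, tuple[dt.date, dt.date]]) -> None:
    """Check that every Ramadan spans 28-30 inclusive days."""
    for year, (start, end) in calendar.items():
        ndays = (end - start).days + 1
        if not 28 <= ndays <= 30:
            raise ValueError(f"Ramadan {year}: {ndays} days, expected 28-30")


def load_calendar(path) -> dict[int, tuple[dt.date, dt.date]]:
    """Load a ``year: {start: ..., end: ...}`` YAML calendar."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    calendar = {}
    for year, entry in raw.items():
        start, end = entry["start"], entry["end"]
        if not isinstance(start, dt.date) or not isinstance(end, dt.date):
            raise ValueError(f"Ramadan {year}: start/end must be ISO dates")
        calendar[int(year)] = (start, end)
    validate_calendar(calendar)
    return calendar


def save_calendar(calendar: dict[int, tuple[dt.date, dt.date]], path) -> None:
    raw = {
        int(y): {"start": s, "end": e} for y, (s, e) in sorted(calendar.items())
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
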