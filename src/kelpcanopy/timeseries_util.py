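"""Interval labeling shared by compositing and timeseries modules.

Annual intervals follow the July–June convention: a year label covers July
of the preceding calendar year through June of the labeled year (the austral
growth season straddles the calendar boundary).  Seasons are austral
quarters: DJF (summer), MAM, JJA, SON.
"""

from __future__ import annotations

import datetime as _dt

__all__ = ["july_june_year", "season_label", "interval_label"]

_SEASONS = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
            6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}


def july_june_year(date: _dt.datetime | _dt.date) -> int:
    """The July–June interval label: months >= July belong to the next year."""
    return date.year + 1 if date.month >= 7 else date.year


def season_label(date: _dt.datetime | _dt.date) -> str:
    """Austral quarter label, e.g. '2018-DJF' (December counts toward the
    following year's summer)."""
    year = date.year + 1 if date.month == 12 else date.year
    return f"{year}-{_SEASONS[date.month]}"


def interval_label(date: _dt.datetime | _dt.date, interval: str) -> str:
    if interval == "annual":
        return str(july_june_year(date))
    if interval == "seasonal":
        return season_label(date)
    raise ValueError(f"interval must be 'annual' or 'seasonal', got {interval!r}")
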