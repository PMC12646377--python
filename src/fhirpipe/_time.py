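"""Timestamp handling.

All timestamps in the pipeline are timezone-aware UTC ``datetime`` objects.
FHIR permits dateTime values at year/month/day/second precision with or
without an offset; everything is normalized here so that window cutoffs are
reproducible: date-only values become 00:00:00 UTC, offset-bearing values
are converted to UTC, naive values are assumed UTC.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

UTC = dt.timezone.utc

DAY = dt.timedelta(days=1)
HOURS_24 = dt.timedelta(hours=24)


def parse_datetime(value: Optional[str]) -> Optional[dt.datetime]:
    """Parse a FHIR date/dateTime/instant string to an aware UTC datetime.

    Returns None for None/empty/unparseable input (callers decide whether
    that is a skip or an error).
    """
    if not value or not isinstance(value, str):
        return None
    text = value.strip()
    if text.endswith(("Z", "z")):
        text = text[:-1] + "+00:00"
    try:
        if len(text) == 4:  # YYYY
            parsed = dt.datetime(int(text), 1, 1)
        elif len(text) == 7:  # YYYY-MM
            year, month = text.split("-")
            parsed = dt.datetime(int(year), int(month), 1)
        else:
            parsed = dt.datetime.fromisoformat(text)
    except ValueError:
        return None
    if parsed.tzinfo is None:
        return parsed.replace(tzinfo=UTC)
    return parsed.astimezone(UTC)


def to_fhir_instant(value: dt.datetime) -> str:
    """Render an aware datetime as a FHIR instant string in UTC."""
    if value.tzinfo is None:
        value = value.replace(tzinfo=UTC)
    value = value.astimezone(UTC)
    return value.strftime("%Y-%m-%dT%H:%M:%S+00:00")


def end_of_utc_day(day: dt.date) -> dt.datetime:
    """23:59:59 UTC of the given calendar date."""
    return dt.datetime(day.year, day.month, day.day, 23, 59, 59, tzinfo=UTC)


def stay_length_days(start: dt.datetime, end: dt.datetime) -> int:
    """Length of stay in days: ceiling of (end - start) / 24h, minimum 0."""
    delta = end - start
    seconds = delta.total_seconds()
    if seconds <= 0:
        return 0
    days, remainder = divmod(seconds, 86400.0)
    return int(days) + (1 if remainder > 0 else 0)


def floored_age_years(birth_date: dt.date, at: dt.datetime) -> int:
    """Age in whole years at a reference instant (floored)."""
    at_date = at.date()
    age = at_date.year - birth_date.year
    if (at_date.month, at_date.day) < (birth_date.month, birth_date.day):
        age -= 1
    return age
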