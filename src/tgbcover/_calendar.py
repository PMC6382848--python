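"""Civil 365-day calendar shared by the rainfall modules.

All daily series use a fixed 365-day year (no leap days); month lengths
follow the civil calendar (Jan=31, Feb=28, ...). At the precision of the
climatological metrics computed here the missing leap day is negligible.
"""

from __future__ import annotations

import numpy as np

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
DAYS_PER_YEAR = 365
DAYS_PER_MONTH_MEAN = DAYS_PER_YEAR / 12.0

#: 0-based start index of each month within a 365-day year, plus the year end.
MONTH_STARTS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)])

#: month number (1..12) of each day of the year.
MONTH_OF_DAY = np.repeat(np.arange(1, 13), MONTH_LENGTHS)


def validate_months(months) -> frozenset[int]:
    """Return ``months`` as a frozenset, checking every entry is in 1..12."""
    months = frozenset(int(m) for m in months)
    if not all(1 <= m <= 12 for m in months):
        raise ValueError(f"month indices must be in 1..12, got {sorted(months)}")
    return months


def days_in_months(months) -> int:
    """Total number of calendar days in the given months (1..12)."""
    months = validate_months(months)
    return int(MONTH_LENGTHS[[m - 1 for m in months]].sum())


def day_mask(months) -> np.ndarray:
    """Boolean mask over the 365 days of a year, True inside ``months``."""
    months = validate_months(months)
    return np.isin(MONTH_OF_DAY, sorted(months))
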