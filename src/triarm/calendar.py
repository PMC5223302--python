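"""Week-index to calendar-month mapping.

Follow-up time is indexed by report week (1-based).  Week 1 is anchored to
the first Monday on or after the first day of a configurable start month,
and the calendar month of a week is the month of that week's Monday.  A
70-week follow-up starting January 2009 therefore spans roughly 16 months,
which is what the seasonality adjustment (calendar month as a fixed effect)
operates on.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

DEFAULT_START_YEAR = 2009
DEFAULT_START_MONTH = 1


def first_monday(year: int, month: int) -> _dt.date:
    """First Monday on or after the first day of the given month."""
    d = _dt.date(year, month, 1)
    return d + _dt.timedelta(days=(7 - d.weekday()) % 7)


def week_monday(week_index: int, start_year: int = DEFAULT_START_YEAR,
                start_month: int = DEFAULT_START_MONTH) -> _dt.date:
    """Monday of a 1-based follow-up week."""
    if week_index < 1:
        raise ValueError(f"week_index must be >= 1, got {week_index}")
    return first_monday(start_year, start_month) + _dt.timedelta(weeks=week_index - 1)


def month_of_week(week_index, start_year: int = DEFAULT_START_YEAR,
                  start_month: int = DEFAULT_START_MONTH):
    """Calendar month (1-12) of one week index or an array of them."""
    if np.isscalar(week_index):
        return week_monday(int(week_index), start_year, start_month).month
    weeks = np.asarray(week_index, dtype=int)
    anchor = first_monday(start_year, start_month)
    # vectorized via ordinal arithmetic
    ordinals = anchor.toordinal() + 7 * (weeks - 1)
    return np.array([_dt.date.fromordinal(int(o)).month for o in ordinals])
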