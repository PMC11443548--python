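"""Calendar helpers shared by the generators and the analysis stages.

The 8-day calendar mirrors the convention of Level-3 mapped ocean-colour
composites: every year is split into 46 fixed steps starting on 1 January,
with the final step absorbing the 1-2 day year-end remainder.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

STEPS_PER_YEAR = 46


def eight_day_step(times: pd.DatetimeIndex) -> np.ndarray:
    """Step-of-year (0..45) for each timestamp."""
    doy = np.asarray(times.dayofyear)
    return np.minimum((doy - 1) // 8, STEPS_PER_YEAR - 1)


def eight_day_dates(start_year: int, n_years: int) -> pd.DatetimeIndex:
    """Start dates of all 46 steps for ``n_years`` consecutive years."""
    dates = []
    for year in range(start_year, start_year + n_years):
        jan1 = pd.Timestamp(year=year, month=1, day=1)
        dates.extend(jan1 + pd.Timedelta(days=8 * k) for k in range(STEPS_PER_YEAR))
    return pd.DatetimeIndex(dates)


def day_of_year_code(times: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year with 29 February pooled into 28 February (codes 1..365)."""
    doy = np.asarray(times.dayofyear)
    leap_shift = np.asarray(times.is_leap_year) & (doy >= 60)
    return doy - leap_shift.astype(int)


def month_code(times: pd.DatetimeIndex) -> np.ndarray:
    return np.asarray(times.month)


def period_codes(times: pd.DatetimeIndex, period_kind: str) -> np.ndarray:
    """Period-of-year codes for a climatology of the given kind."""
    if period_kind == "day-of-year":
        return day_of_year_code(times)
    if period_kind == "8-day-step":
        return eight_day_step(times)
    if period_kind == "month":
        return month_code(times)
    raise ValueError(
        f"unknown period_kind {period_kind!r}; "
        "expected 'day-of-year', '8-day-step' or 'month'"
    )
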