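"""Calendar arithmetic helpers shared by cohort building, costing and simulation.

All date columns are pandas ``datetime64[ns]``; intervals are half-open
``[start, end)``.  Year/month offsets are calendrical: the day-of-month is
preserved and clamped to the end of the target month (so 31 Mar - 2 months is
31 Jan, while 31 May + 1 month is 30 Jun, and 29 Feb + n years falls back to
28 Feb in non-leap years).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def is_leap(year) -> np.ndarray:
    y = np.asarray(year)
    return (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))


def days_in_year(year):
    """Number of days in the calendar year (365 or 366); scalar or array."""
    return np.where(is_leap(year), 366, 365)


def year_start(year) -> pd.Timestamp:
    return pd.Timestamp(int(year), 1, 1)


def _build(year, month, day) -> pd.Series:
    frame = pd.DataFrame({"year": year, "month": month, "day": day})
    return pd.to_datetime(frame, errors="coerce")


def _clamped(year, month, day) -> pd.Series:
    """Date from components with the day clamped to the month's last day."""
    out = _build(year, month, day)
    for fallback in (30, 29, 28):
        bad = out.isna().to_numpy()
        if not bad.any():
            break
        out[bad] = _build(
            np.asarray(year)[bad],
            np.asarray(month)[bad],
            np.minimum(np.asarray(day)[bad], fallback),
        ).to_numpy()
    return out


def add_years(dates, n: int) -> pd.Series:
    """Calendrical anniversary: same month/day ``n`` years later (day clamped)."""
    s = pd.Series(pd.to_datetime(dates))
    out = pd.Series(pd.NaT, index=s.index, dtype="datetime64[ns]")
    ok = s.notna()
    if ok.any():
        d = s[ok].dt
        res = _clamped(d.year.to_numpy() + n, d.month.to_numpy(), d.day.to_numpy())
        out[ok.to_numpy()] = res.to_numpy()
    return out


def add_months(dates, n: int) -> pd.Series:
    """Same day-of-month ``n`` calendar months away, clamped to month end."""
    s = pd.Series(pd.to_datetime(dates))
    out = pd.Series(pd.NaT, index=s.index, dtype="datetime64[ns]")
    ok = s.notna()
    if ok.any():
        d = s[ok].dt
        total = d.year.to_numpy() * 12 + (d.month.to_numpy() - 1) + n
        res = _clamped(total // 12, total % 12 + 1, d.day.to_numpy())
        out[ok.to_numpy()] = res.to_numpy()
    return out


def overlap_days(a_start, a_end, b_start, b_end):
    """Length in days of the intersection of half-open intervals, floored at 0.

    Accepts scalars/arrays of datetime64; returns float days.
    """
    lo = np.maximum(np.asarray(a_start, dtype="datetime64[ns]"), np.asarray(b_start, dtype="datetime64[ns]"))
    hi = np.minimum(np.asarray(a_end, dtype="datetime64[ns]"), np.asarray(b_end, dtype="datetime64[ns]"))
    delta = (hi - lo) / np.timedelta64(1, "D")
    return np.maximum(delta, 0.0)


def age_on(dates, birth_dates):
    """Attained age in whole years on ``dates`` (floor of fractional age)."""
    d = np.asarray(pd.to_datetime(dates), dtype="datetime64[ns]")
    b = np.asarray(pd.to_datetime(birth_dates), dtype="datetime64[ns]")
    frac = (d - b) / np.timedelta64(1, "D") / 365.25
    return np.floor(frac).astype(int)
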