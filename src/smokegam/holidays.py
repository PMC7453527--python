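"""Holiday indicator construction for the calendar part of the model.

The default set contains 17 holidays: the 10 US federal holidays plus
Christmas Eve, New Year's Eve, the day after Thanksgiving, Easter Sunday,
Halloween, Cinco de Mayo, and Super Bowl Sunday.  The set is configurable;
each holiday contributes one 0/1 indicator column.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_HOLIDAYS", "holiday_dates", "holiday_indicators", "easter_sunday"]


def _nth_weekday(year: int, month: int, weekday: int, n: int) -> dt.date:
    """n-th (1-based) occurrence of ``weekday`` (Mon=0) in a month."""
    first = dt.date(year, month, 1)
    offset = (weekday - first.weekday()) % 7
    return first + dt.timedelta(days=offset + 7 * (n - 1))


def _last_weekday(year: int, month: int, weekday: int) -> dt.date:
    next_month = dt.date(year + month // 12, month % 12 + 1, 1)
    last = next_month - dt.timedelta(days=1)
    return last - dt.timedelta(days=(last.weekday() - weekday) % 7)


def easter_sunday(year: int) -> dt.date:
    """Gregorian Easter via the anonymous computus."""
    a = year % 19
    b, c = divmod(year, 100)
    d, e = divmod(b, 4)
    g = (8 * b + 13) // 25
    h = (19 * a + b - d - g + 15) % 30
    i, k = divmod(c, 4)
    l = (32 + 2 * e + 2 * i - h - k) % 7
    m = (a + 11 * h + 22 * l) // 451
    month, day = divmod(h + l - 7 * m + 114, 31)
    return dt.date(year, month, day + 1)


def _thanksgiving(year: int) -> dt.date:
    return _nth_weekday(year, 11, 3, 4)  # 4th Thursday of November


_RULES = {
    "new_years_day": lambda y: dt.date(y, 1, 1),
    "mlk_day": lambda y: _nth_weekday(y, 1, 0, 3),
    "presidents_day": lambda y: _nth_weekday(y, 2, 0, 3),
    "memorial_day": lambda y: _last_weekday(y, 5, 0),
    "independence_day": lambda y: dt.date(y, 7, 4),
    "labor_day": lambda y: _nth_weekday(y, 9, 0, 1),
    "columbus_day": lambda y: _nth_weekday(y, 10, 0, 2),
    "veterans_day": lambda y: dt.date(y, 11, 11),
    "thanksgiving": _thanksgiving,
    "christmas": lambda y: dt.date(y, 12, 25),
    "christmas_eve": lambda y: dt.date(y, 12, 24),
    "new_years_eve": lambda y: dt.date(y, 12, 31),
    "day_after_thanksgiving": lambda y: _thanksgiving(y) + dt.timedelta(days=1),
    "easter": easter_sunday,
    "halloween": lambda y: dt.date(y, 10, 31),
    "cinco_de_mayo": lambda y: dt.date(y, 5, 5),
    "super_bowl_sunday": lambda y: _nth_weekday(y, 2, 6, 1),
}

DEFAULT_HOLIDAYS: tuple[str, ...] = tuple(_RULES)


def holiday_dates(name: str, years) -> list[dt.date]:
    """Observed dates of one holiday over an iterable of years."""
    try:
        rule = _RULES[name]
    except KeyError:
        raise KeyError(f"unknown holiday {name!r}; known: {sorted(_RULES)}") from None
    return [rule(int(y)) for y in years]


def holiday_indicators(dates: pd.DatetimeIndex, holidays=DEFAULT_HOLIDAYS) -> pd.DataFrame:
    """One 0/1 indicator column per holiday, indexed by ``dates``."""
    dates = pd.DatetimeIndex(dates)
    years = range(dates.year.min(), dates.year.max() + 1) if len(dates) else []
    out = pd.DataFrame(0, index=dates, columns=list(holidays), dtype=np.int8)
    for name in holidays:
        hits = pd.DatetimeIndex([pd.Timestamp(d) for d in holiday_dates(name, years)])
        out.loc[dates.isin(hits), name] = 1
    return out
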