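"""Calendar-month helpers shared across the pipeline.

Months are passed around as ``yyyymm`` integers (e.g. ``201805``); internally
arithmetic uses a flat month index ``year*12 + (month-1)`` so that consecutive
calendar months differ by exactly 1.
"""

from __future__ import annotations

import pandas as pd


def ym_to_idx(ym: int) -> int:
    """Flat month index of a yyyymm integer."""
    year, month = divmod(int(ym), 100)
    if not 1 <= month <= 12:
        raise ValueError(f"invalid yyyymm month: {ym}")
    return year * 12 + (month - 1)


def idx_to_ym(idx: int) -> int:
    year, month0 = divmod(int(idx), 12)
    return year * 100 + (month0 + 1)


def ym_add(ym: int, months: int) -> int:
    return idx_to_ym(ym_to_idx(ym) + months)


def ym_diff(a: int, b: int) -> int:
    """Number of calendar months from *b* to *a*."""
    return ym_to_idx(a) - ym_to_idx(b)


def ym_range(start: int, end: int) -> list[int]:
    """All months from start to end inclusive."""
    return [idx_to_ym(i) for i in range(ym_to_idx(start), ym_to_idx(end) + 1)]


def month_start(ym: int) -> pd.Timestamp:
    year, month = divmod(int(ym), 100)
    return pd.Timestamp(year=year, month=month, day=1)


def month_end(ym: int) -> pd.Timestamp:
    """Last instant strictly before the next month starts (first day of next month)."""
    return month_start(ym_add(ym, 1))


def date_to_ym(dates) -> "pd.Series | int":
    """yyyymm of a Timestamp or datetime Series."""
    if isinstance(dates, pd.Series):
        return dates.dt.year * 100 + dates.dt.month
    ts = pd.Timestamp(dates)
    return ts.year * 100 + ts.month
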