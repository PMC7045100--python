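"""Calendar-month helpers shared across the package.

Months are represented as :class:`pandas.Period` objects with monthly
frequency.  Public functions accept either a Period or anything
``pandas.Period`` can parse (e.g. ``"2012-04"``).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

__all__ = ["to_month", "month_range", "is_contiguous"]


def to_month(value) -> pd.Period:
    """Coerce ``value`` to a monthly :class:`pandas.Period`."""
    if isinstance(value, pd.Period):
        if value.freqstr.upper().startswith("M"):
            return value
        return value.asfreq("M")
    return pd.Period(value, freq="M")


def month_range(start, end) -> list[pd.Period]:
    """Inclusive list of calendar months from ``start`` to ``end``."""
    start, end = to_month(start), to_month(end)
    if end < start:
        raise ValueError(f"end month {end} precedes start month {start}")
    return list(pd.period_range(start, end, freq="M"))


def is_contiguous(months: Sequence[pd.Period]) -> bool:
    months = [to_month(m) for m in months]
    return all(b == a + 1 for a, b in zip(months, months[1:]))


def as_months(values: Iterable) -> list[pd.Period]:
    return [to_month(v) for v in values]
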