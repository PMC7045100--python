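"""Data temporal maps: per-month empirical joint distributions.

A data temporal map (DTM) stacks the empirical joint probability
distribution of a fixed set of categorical variables, one row per calendar
month, over a support aligned across all months (the union of the cells
observed in any month, ordered lexicographically by variable order then
declared category order).  Each row is the month's joint histogram divided
by the month's total observation count.  No smoothing is applied by
default: a cell never observed in a month is exactly zero, and counts are
exactly recoverable from probabilities times denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._months import to_month
from .slicing import MonthlySlice, VariableSchema

__all__ = ["DataTemporalMap", "estimate_dtm", "marginalize"]

_ROWSUM_ATOL = 1e-9


@dataclass(frozen=True)
class DataTemporalMap:
    """Months x aligned-support matrix of counts and probabilities.

    Attributes
    ----------
    months
        Ordered non-empty calendar months.
    support
        Ordered category tuples (cells of the joint), identical for every
        month; single categories are represented as 1-tuples.
    counts
        Integer matrix, ``len(months) x len(support)``.
    schema
        The variable names and category sets behind the support.
    """

    months: tuple[pd.Period, ...]
    support: tuple[tuple, ...]
    counts: np.ndarray
    schema: VariableSchema

    def __post_init__(self):
        object.__setattr__(self, "months", tuple(to_month(m) for m in self.months))
        object.__setattr__(self, "support", tuple(tuple(c) for c in self.support))
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.months), len(self.support)):
            raise ValueError(
                f"counts shape {counts.shape} != ({len(self.months)}, {len(self.support)})"
            )
        if np.any(counts < 0):
            raise ValueError("negative counts")
        if np.any(counts.sum(axis=1) == 0):
            raise ValueError("DataTemporalMap rows must be non-empty months")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def denominators(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def probabilities(self) -> np.ndarray:
        p = self.counts / self.denominators[:, None]
        assert np.all(np.abs(p.sum(axis=1) - 1.0) < _ROWSUM_ATOL)
        return p

    def row(self, month) -> np.ndarray:
        """Probability row for one month."""
        m = to_month(month)
        try:
            i = self.months.index(m)
        except ValueError:
            raise KeyError(f"month {m} not in this temporal map") from None
        return self.probabilities[i]

    def to_frame(self, kind: str = "probabilities") -> pd.DataFrame:
        data = self.probabilities if kind == "probabilities" else self.counts
        cols = ["|".join(str(c) for c in cell) for cell in self.support]
        return pd.DataFrame(data, index=pd.PeriodIndex(self.months, freq="M"), columns=cols)


def estimate_dtm(
    slices: Sequence[MonthlySlice], variables: Sequence[str] | None = None
) -> DataTemporalMap:
    """Estimate the data temporal map from monthly slices.

    Each row is the month's joint histogram over ``variables`` divided by
    the month's denominator.  Empty slices (zero denominator) are excluded
    with a warning; the support is the union of cells observed in any
    retained month.

    Parameters
    ----------
    slices
        Monthly slices sharing one variable schema.
    variables
        Optional ordered subset of schema variables; cells are aggregated
        over the omitted variables.  Default: all schema variables.
    """
    if not slices:
        raise ValueError("no slices given")
    schema = slices[0].schema
    if any(s.schema != schema for s in slices):
        raise ValueError("all slices must share one variable schema")
    if variables is None:
        variables = schema.variables
        sub = schema
    else:
        sub = schema.subset(variables)
    positions = [schema.variables.index(v) for v in sub.variables]

    kept: list[MonthlySlice] = []
    for s in slices:
        if s.is_empty:
            warnings.warn(f"excluding empty month {s.month} from the temporal map")
        else:
            kept.append(s)
    if not kept:
        raise ValueError("all slices are empty")

    aggregated: list[dict[tuple, int]] = []
    support: set[tuple] = set()
    for s in kept:
        agg: dict[tuple, int] = {}
        for cell, v in s.counts.items():
            key = tuple(cell[p] for p in positions)
            agg[key] = agg.get(key, 0) + v
        aggregated.append(agg)
        support.update(agg)

    ordered = tuple(sorted(support, key=sub.sort_key))
    col = {cell: j for j, cell in enumerate(ordered)}
    counts = np.zeros((len(kept), len(ordered)), dtype=np.int64)
    for i, agg in enumerate(aggregated):
        for cell, v in agg.items():
            counts[i, col[cell]] = v
    return DataTemporalMap(tuple(s.month for s in kept), ordered, counts, sub)


def marginalize(dtm: DataTemporalMap, variables) -> DataTemporalMap:
    """Collapse a joint DTM onto one variable (or an ordered subset).

    Each marginal cell is the sum of the joint cells consistent with it;
    row sums are preserved at 1 exactly because counts are summed before
    normalisation.
    """
    if isinstance(variables, str):
        variables = (variables,)
    sub = dtm.schema.subset(variables)
    positions = [dtm.schema.variables.index(v) for v in sub.variables]

    keys = [tuple(cell[p] for p in positions) for cell in dtm.support]
    ordered = tuple(sorted(set(keys), key=sub.sort_key))
    col = {cell: j for j, cell in enumerate(ordered)}
    counts = np.zeros((len(dtm.months), len(ordered)), dtype=np.int64)
    for j_src, key in enumerate(keys):
        counts[:, col[key]] += dtm.counts[:, j_src]
    return DataTemporalMap(dtm.months, ordered, counts, sub)
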