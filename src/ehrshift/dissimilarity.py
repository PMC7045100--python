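"""Jensen-Shannon dissimilarities between monthly distributions.

The temporal-variability metric compares the empirical distribution of one
month with that of another using the Jensen-Shannon construction: the mean
of the two Kullback-Leibler divergences to the midpoint mixture.  With log
base 2 the divergence lies in [0, 1], where 0 means identical distributions
and 1 means distributions with no overlapping support.  Its square root is a
metric (it satisfies the triangle inequality) and is the scale used when a
Euclidean embedding is required; the divergence scale is used when reporting
average month-to-month rates of change.

Two scales are therefore exposed everywhere and always labelled:

``divergence``
    the Jensen-Shannon divergence itself (bounded by 1 in base 2);
``distance``
    its square root, a metric suitable for multidimensional scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from ._months import is_contiguous, to_month

__all__ = [
    "js_divergence",
    "js_distance",
    "pairwise_matrix",
    "consecutive_series",
    "mean_rate",
    "DissimilarityMatrix",
]

_NORM_ATOL = 1e-9


def _validated_pair(p, q) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.ndim != 1 or q.ndim != 1:
        raise ValueError("probability vectors must be one-dimensional")
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape[0]} vs {q.shape[0]}")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0):
            raise ValueError(f"{name} has negative entries")
        if abs(v.sum() - 1.0) > _NORM_ATOL:
            raise ValueError(f"{name} does not sum to 1 (sum={v.sum()!r})")
    return p, q


def js_divergence(p: Sequence[float], q: Sequence[float], log_base: float = 2) -> float:
    """Jensen-Shannon divergence between two probability vectors.

    Computed as ``0.5*KL(p||m) + 0.5*KL(q||m)`` with ``m = (p+q)/2`` and the
    convention ``0*log(0/x) = 0``.  The mixture ``m`` is strictly positive
    wherever either input is, so no other singularities arise.

    Parameters
    ----------
    p, q
        Non-negative vectors of equal length, each summing to 1 (within 1e-9).
    log_base
        Base of the logarithm; 2 (default) bounds the result by 1, ``math.e``
        bounds it by ln 2.
    """
    p, q = _validated_pair(p, q)
    m = 0.5 * (p + q)
    # rel_entr implements x*log(x/y) in nats with the 0*log0 convention.
    d_nats = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum())
    d = d_nats / math.log(log_base)
    # Guard against -eps from floating point cancellation near identity.
    return max(d, 0.0)


def js_distance(p: Sequence[float], q: Sequence[float], log_base: float = 2) -> float:
    """Jensen-Shannon distance: the square root of :func:`js_divergence`.

    A true metric on probability vectors, hence embeddable in Euclidean
    space by classical multidimensional scaling.
    """
    return math.sqrt(js_divergence(p, q, log_base=log_base))


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric month-by-month Jensen-Shannon dissimilarity matrix.

    Attributes
    ----------
    months
        Ordered calendar months (one per row/column).
    values
        Square symmetric matrix with zero diagonal.
    scale
        ``"divergence"`` or ``"distance"``.
    log_base
        Logarithm base used (2 or e).
    """

    months: tuple[pd.Period, ...]
    values: np.ndarray
    scale: str = "distance"
    log_base: float = 2
    _SYM_ATOL = 1e-12

    def __post_init__(self):
        object.__setattr__(self, "months", tuple(to_month(m) for m in self.months))
        v = np.asarray(self.values, dtype=float)
        n = len(self.months)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} months")
        if self.scale not in ("divergence", "distance"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not np.allclose(v, v.T, atol=self._SYM_ATOL):
            raise ValueError("matrix is not symmetric")
        if np.any(np.abs(np.diag(v)) > self._SYM_ATOL):
            raise ValueError("matrix diagonal is not zero")
        if np.any(v < -self._SYM_ATOL):
            raise ValueError("negative dissimilarities")
        if self.log_base == 2 and np.any(v > 1 + 1e-9):
            raise ValueError("entries exceed the base-2 bound of 1")
        object.__setattr__(self, "values", v)

    @property
    def n_months(self) -> int:
        return len(self.months)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.PeriodIndex(self.months, freq="M")
        return pd.DataFrame(self.values, index=idx, columns=idx)

    def as_scale(self, scale: str) -> "DissimilarityMatrix":
        """Return this matrix on the requested scale (square/square-root)."""
        if scale == self.scale:
            return self
        if scale == "distance":
            return DissimilarityMatrix(self.months, np.sqrt(self.values), scale, self.log_base)
        if scale == "divergence":
            return DissimilarityMatrix(self.months, self.values**2, scale, self.log_base)
        raise ValueError(f"unknown scale {scale!r}")


def pairwise_matrix(dtm, scale: str = "distance", log_base: float = 2) -> DissimilarityMatrix:
    """All pairwise Jensen-Shannon dissimilarities between a DTM's months.

    Uses the entropy identity ``JS(p, q) = H((p+q)/2) - (H(p) + H(q))/2`` for
    an O(n^2 * s) vectorised evaluation over the aligned support.

    Parameters
    ----------
    dtm
        A :class:`~ehrshift.temporal_map.DataTemporalMap` with at least two
        non-empty months.
    scale
        ``"distance"`` (default; metric, for embedding) or ``"divergence"``
        (for rate statistics).
    """
    P = np.asarray(dtm.probabilities, dtype=float)
    months = dtm.months
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 months to form a dissimilarity matrix")

    def entropy_rows(mat: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(mat > 0, mat * np.log(mat), 0.0)
        return -t.sum(axis=1)

    h = entropy_rows(P)
    vals = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        m = 0.5 * (P[i][None, :] + P[i + 1 :])
        js = entropy_rows(m) - 0.5 * (h[i] + h[i + 1 :])
        vals[i, i + 1 :] = js
    vals = (vals + vals.T) / math.log(log_base)
    np.fill_diagonal(vals, 0.0)
    vals = np.clip(vals, 0.0, None)
    if scale == "distance":
        vals = np.sqrt(vals)
    elif scale != "divergence":
        raise ValueError(f"unknown scale {scale!r}")
    return DissimilarityMatrix(tuple(months), vals, scale=scale, log_base=log_base)


def consecutive_series(matrix: DissimilarityMatrix) -> pd.Series:
    """Month-to-month dissimilarity series (the matrix superdiagonal).

    The series is indexed by the *later* month of each step.  Calendar gaps
    in the month list split the series: a step across a gap is omitted.
    """
    months = matrix.months
    if len(months) < 2:
        raise ValueError("need at least 2 months")
    steps, vals = [], []
    for i in range(len(months) - 1):
        if months[i + 1] == months[i] + 1:
            steps.append(months[i + 1])
            vals.append(matrix.values[i, i + 1])
    if not is_contiguous(months):
        # gaps were skipped above; nothing else to do, just be explicit
        pass
    return pd.Series(vals, index=pd.PeriodIndex(steps, freq="M"), name=f"jsd_{matrix.scale}")


def mean_rate(series: pd.Series, period: tuple | None = None) -> float:
    """Average dissimilarity per month over ``period``.

    ``period`` is an inclusive ``(start, end)`` pair of months compared
    against the step's later-month index; ``None`` averages the whole series.
    """
    if period is not None:
        start, end = to_month(period[0]), to_month(period[1])
        series = series[(series.index >= start) & (series.index <= end)]
    if len(series) == 0:
        raise ValueError("no consecutive month-steps fall inside the requested period")
    return float(series.mean())
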