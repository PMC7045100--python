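"""Information-geometric temporal (IGT) embedding.

The month-by-month Jensen-Shannon distance matrix is mapped into a low
(2-3) dimensional Euclidean space by classical (Torgerson) multidimensional
scaling: square the dissimilarities, double-centre, eigendecompose, and
scale the leading eigenvectors by the square roots of their eigenvalues.
Plotting the months in this space and joining them in calendar order gives
the temporal trajectory of the data distribution; gradual drifts appear as
smooth paths, abrupt changes as long jumps between point clouds, and
seasonal effects as cyclic structure.

Axis orientation is arbitrary (MDS is defined up to rotation/reflection);
for serialization stability each dimension is oriented so its
largest-magnitude coordinate is positive.  Comparisons of embeddings should
always be made on inter-point distances or after Procrustes alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from ._months import to_month
from .dissimilarity import DissimilarityMatrix

__all__ = ["IGTEmbedding", "classical_mds", "label_months", "trajectory", "MONTH_GLYPHS"]

#: one glyph per calendar month, Jan..Dec (lowercase m/j/a disambiguate
#: May/June/August from March/January/April; x stands for July)
MONTH_GLYPHS = "JFMAmjxaSOND"

#: clamped negative-eigenvalue mass above this fraction of the total
#: triggers a non-metric-input warning
NEGATIVE_MASS_WARN = 0.10


@dataclass(frozen=True)
class IGTEmbedding:
    """Low-dimensional Euclidean coordinates of the monthly distributions.

    Attributes
    ----------
    months : ordered calendar months.
    coordinates : ``len(months) x dims`` array.
    eigenvalues : all eigenvalues of the double-centred matrix, sorted
        non-increasing, negatives clamped to zero.
    variance_explained : per-retained-dimension fraction of the positive
        eigenvalue mass, non-increasing.
    month_labels : glyph label per month (e.g. ``"12A"`` for April 2012).
    clamped_negative_mass : fraction of total absolute eigenvalue mass that
        was negative and clamped (diagnostic for non-metric input).
    """

    months: tuple[pd.Period, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    month_labels: tuple[str, ...]
    clamped_negative_mass: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "months", tuple(to_month(m) for m in self.months))
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[0] != len(self.months):
            raise ValueError("coordinates must be a months x dims matrix")
        if coords.shape[1] > len(self.months) - 1:
            raise ValueError("dims must not exceed number of months - 1")
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev < 0):
            raise ValueError("eigenvalues must already be clamped to >= 0")
        if np.any(np.diff(ev) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")
        ve = np.asarray(self.variance_explained, dtype=float)
        if np.any((ve < 0) | (ve > 1)) or np.any(np.diff(ve) > 1e-12):
            raise ValueError("variance_explained must be non-increasing fractions in [0,1]")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "eigenvalues", ev)
        object.__setattr__(self, "variance_explained", ve)
        object.__setattr__(self, "month_labels", tuple(self.month_labels))

    @property
    def dims(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            index=pd.PeriodIndex(self.months, freq="M"),
            columns=[f"dim{i + 1}" for i in range(self.dims)],
        )
        df.insert(0, "label", list(self.month_labels))
        return df


def label_months(months: Sequence) -> list[str]:
    """Compact month labels: two-digit year plus a one-glyph month.

    The glyph alphabet is ``J F M A m j x a S O N D`` for January..December
    (July is ``x``; May, June and August are lowercase to stay unique).
    """
    out = []
    for m in months:
        m = to_month(m)
        out.append(f"{m.year % 100:02d}{MONTH_GLYPHS[m.month - 1]}")
    return out


def classical_mds(matrix: DissimilarityMatrix, dims: int = 3) -> IGTEmbedding:
    """Torgerson classical MDS of a month dissimilarity matrix.

    Squares the dissimilarities, double-centres (``B = -1/2 J D^2 J``),
    eigendecomposes, and returns the top ``dims`` eigenvectors scaled by the
    square roots of their (clamped) eigenvalues.  Negative eigenvalues --
    which arise when the input is not a Euclidean-embeddable metric, e.g.
    when the divergence scale is used instead of the distance scale -- are
    clamped to zero and their mass reported; above 10% of the total a
    warning is emitted.

    Parameters
    ----------
    matrix
        Dissimilarity matrix (distance scale recommended).
    dims
        Number of retained dimensions, default 3; must be at most
        ``n_months - 1``.
    """
    n = matrix.n_months
    if dims < 1:
        raise ValueError("dims must be >= 1")
    if dims > n - 1:
        raise ValueError(f"dims={dims} exceeds n_months-1={n - 1}")
    d2 = matrix.values.astype(float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2  # enforce symmetry against rounding
    w, v = eigh(b)
    order = np.argsort(w)[::-1]  # stable ordering: eigenvalue desc, then index
    w, v = w[order], v[:, order]

    total_abs = np.abs(w).sum()
    neg_mass = float(-w[w < 0].sum() / total_abs) if total_abs > 0 else 0.0
    if neg_mass > NEGATIVE_MASS_WARN:
        warnings.warn(
            f"{neg_mass:.1%} of the eigenvalue mass is negative and was clamped; "
            "the input matrix is probably on the (non-metric) divergence scale"
        )
    w_clamped = np.clip(w, 0.0, None)

    coords = v[:, :dims] * np.sqrt(w_clamped[:dims])[None, :]
    # fixed sign convention: largest-magnitude coordinate of each dimension positive
    for k in range(dims):
        col = coords[:, k]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, k] = -col
    pos_total = w_clamped.sum()
    var_exp = w_clamped[:dims] / pos_total if pos_total > 0 else np.zeros(dims)
    return IGTEmbedding(
        months=tuple(matrix.months),
        coordinates=coords,
        eigenvalues=w_clamped,
        variance_explained=var_exp,
        month_labels=tuple(label_months(matrix.months)),
        clamped_negative_mass=neg_mass,
    )


def trajectory(embedding: IGTEmbedding) -> list[np.ndarray]:
    """Calendar-ordered polyline(s) through the embedded months.

    Returns a list of coordinate arrays, one per run of contiguous months;
    calendar gaps (months excluded upstream, e.g. empty months) break the
    polyline rather than drawing a segment across the gap.
    """
    if len(embedding.months) < 2:
        raise ValueError("need at least 2 months for a trajectory")
    segments: list[np.ndarray] = []
    start = 0
    for i in range(1, len(embedding.months)):
        if embedding.months[i] != embedding.months[i - 1] + 1:
            segments.append(embedding.coordinates[start:i])
            start = i
    segments.append(embedding.coordinates[start:])
    return segments
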