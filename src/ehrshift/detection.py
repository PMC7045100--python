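"""Reproducible change detection on temporal-variability output.

Visual inspection of information-geometric temporal plots is replaced by
four rule-based detectors in the spirit of statistical process control:

- **abrupt changes**: month-steps whose consecutive Jensen-Shannon value
  exceeds a robust control limit (median + k * 1.4826 * MAD of the series);
- **gradual trends**: a strong Spearman rank correlation between calendar
  order and the first embedding dimension;
- **period clusters**: a candidate grouping of months (calendar year, NHS
  financial year, month-of-year, or user supplied) whose silhouette score
  on the dissimilarity matrix is high;
- **source attribution**: re-evaluating a flagged month-step on each
  single-variable marginal to rank the variables driving it.

The thresholds (k = 5, |rho| >= 0.8, silhouette >= 0.5) are this package's
defaults, justified by the null-scenario calibration suite; all are
exposed as parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

from ._months import to_month
from .dissimilarity import (
    DissimilarityMatrix,
    consecutive_series,
    js_divergence,
    pairwise_matrix,
)
from .igt import IGTEmbedding, classical_mds
from .temporal_map import DataTemporalMap, marginalize

__all__ = [
    "Flag",
    "ChangeReport",
    "detect_abrupt",
    "detect_trend",
    "detect_period_clusters",
    "attribute_source",
    "calendar_year_grouping",
    "financial_year_grouping",
    "month_of_year_grouping",
    "analyze",
]

FLAG_KINDS = ("abrupt", "trend", "cluster", "subgroup", "outlier")


@dataclass(frozen=True)
class Flag:
    """One detected deviation.

    ``location`` is the later month of a flagged step (abrupt), a
    ``(start, end)`` period (trend), or a grouping name (cluster).
    ``attributed_variables`` is a ranked ``(variable, score)`` tuple list
    when attribution has been run.
    """

    kind: str
    location: object
    score: float
    attributed_variables: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.kind not in FLAG_KINDS:
            raise ValueError(f"unknown flag kind {self.kind!r}")
        if not np.isfinite(self.score):
            raise ValueError("flag score must be finite")


@dataclass(frozen=True)
class ChangeReport:
    """Collection of flags produced by the detectors."""

    flags: tuple[Flag, ...] = ()

    def of_kind(self, kind: str) -> tuple[Flag, ...]:
        return tuple(f for f in self.flags if f.kind == kind)

    def __len__(self) -> int:
        return len(self.flags)

    def merged(self, other: "ChangeReport") -> "ChangeReport":
        return ChangeReport(self.flags + other.flags)

    def to_records(self) -> list[dict]:
        return [
            {
                "kind": f.kind,
                "location": str(f.location),
                "score": float(f.score),
                "attributed_variables": [[v, float(s)] for v, s in f.attributed_variables],
            }
            for f in self.flags
        ]


def detect_abrupt(series: pd.Series, k: float = 5.0) -> ChangeReport:
    """Flag spikes in a consecutive-month dissimilarity series.

    A month-step is flagged when its value exceeds
    ``median + k * 1.4826 * MAD`` with both statistics computed on the full
    series (1.4826 scales the median absolute deviation to a standard
    deviation under normality).  For a constant series (MAD = 0) the rule
    degenerates to flagging any value strictly above the median.

    The score is the robust z-score ``(value - median) / (1.4826 * MAD)``,
    or the raw excess over the median in the degenerate case.
    """
    if len(series) < 12:
        raise ValueError("abrupt-change detection needs a series of at least 12 steps")
    x = series.to_numpy(dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    flags = []
    if mad == 0.0:
        for loc, v in series.items():
            if v > med:
                flags.append(Flag("abrupt", loc, float(v - med)))
    else:
        sigma = 1.4826 * mad
        for loc, v in series.items():
            z = (v - med) / sigma
            if z > k:
                flags.append(Flag("abrupt", loc, float(z)))
    return ChangeReport(tuple(flags))


def detect_trend(
    embedding: IGTEmbedding,
    period: tuple | None = None,
    rho_threshold: float = 0.8,
) -> ChangeReport:
    """Flag a gradual drift: |Spearman rho| between time and dimension 1.

    ``period`` restricts the test to an inclusive month interval; at least
    12 months are required.  The flag's score is the signed rho, so a
    drift-and-reversal can be localised by testing sub-periods split at the
    suspected turning point.
    """
    months = list(embedding.months)
    coords = embedding.coordinates[:, 0]
    if period is not None:
        a, b = to_month(period[0]), to_month(period[1])
        sel = [i for i, m in enumerate(months) if a <= m <= b]
        months = [months[i] for i in sel]
        coords = coords[sel]
    if len(months) < 12:
        raise ValueError("trend detection needs at least 12 months in the period")
    rho = spearmanr(np.arange(len(months)), coords).statistic
    flags = ()
    if abs(rho) >= rho_threshold:
        flags = (Flag("trend", (months[0], months[-1]), float(rho)),)
    return ChangeReport(flags)


def calendar_year_grouping(months: Sequence) -> list:
    return [to_month(m).year for m in months]


def financial_year_grouping(
    months: Sequence, start_month: int = 4, years_per_group: int = 1, anchor_year: int | None = None
) -> list:
    """Label months by (multi-year blocks of) NHS financial years (Apr-Mar)."""
    labels = []
    fy_starts = []
    for m in months:
        m = to_month(m)
        fy = m.year if m.month >= start_month else m.year - 1
        fy_starts.append(fy)
    base = anchor_year if anchor_year is not None else min(fy_starts)
    for fy in fy_starts:
        labels.append(base + ((fy - base) // years_per_group) * years_per_group)
    return labels


def month_of_year_grouping(months: Sequence) -> list:
    """Seasonality candidate: group by calendar month-of-year."""
    return [to_month(m).month for m in months]


def detect_period_clusters(
    matrix: DissimilarityMatrix,
    candidate_groupings: Mapping[str, Sequence] | None = None,
    silhouette_threshold: float = 0.5,
) -> ChangeReport:
    """Flag candidate period groupings that cluster the months tightly.

    Each candidate grouping assigns a label to every month of the matrix;
    the silhouette score (on the precomputed dissimilarities) compares mean
    within-group to between-group dissimilarity.  Groups with a single
    month are excluded with a warning; a grouping reduced to fewer than two
    groups is rejected.

    Default candidates: calendar year, NHS financial year (April-March),
    and month-of-year (seasonality).
    """
    months = matrix.months
    if candidate_groupings is None:
        candidate_groupings = {
            "calendar_year": calendar_year_grouping(months),
            "financial_year": financial_year_grouping(months),
            "month_of_year": month_of_year_grouping(months),
        }
    flags = []
    for name, labels in candidate_groupings.items():
        labels = np.asarray(list(labels))
        if len(labels) != len(months):
            raise ValueError(f"grouping {name!r} does not label every month")
        uniq, counts = np.unique(labels, return_counts=True)
        singles = uniq[counts == 1]
        keep = ~np.isin(labels, singles)
        if len(singles):
            warnings.warn(
                f"grouping {name!r}: excluding singleton groups {list(singles)} "
                "from the silhouette computation"
            )
        kept_labels = labels[keep]
        if len(np.unique(kept_labels)) < 2:
            raise ValueError(f"grouping {name!r} has fewer than two usable groups")
        sub = matrix.values[np.ix_(keep, keep)]
        score = float(silhouette_score(sub, kept_labels, metric="precomputed"))
        if score >= silhouette_threshold:
            flags.append(Flag("cluster", name, score))
    return ChangeReport(tuple(flags))


def attribute_source(
    dtm: DataTemporalMap,
    location,
    log_base: float = 2,
) -> tuple[tuple[str, float], ...]:
    """Rank variables by their marginal dissimilarity at a flagged step.

    ``location`` is the later month of the step (the preceding calendar
    month is the comparator) or an explicit ``(month_a, month_b)`` pair.
    For each schema variable the joint map is marginalised onto it and the
    Jensen-Shannon divergence between the two months' marginals computed;
    variables are returned ranked by that score, largest first.
    """
    if isinstance(location, (tuple, list)):
        m_a, m_b = to_month(location[0]), to_month(location[1])
    else:
        m_b = to_month(location)
        m_a = m_b - 1
    scores = []
    for var in dtm.schema.variables:
        marg = marginalize(dtm, var)
        d = js_divergence(marg.row(m_a), marg.row(m_b), log_base=log_base)
        scores.append((var, d))
    scores.sort(key=lambda t: -t[1])
    return tuple(scores)


def category_contributions(
    dtm: DataTemporalMap, variable: str, location, log_base: float = 2
) -> tuple[tuple[object, float], ...]:
    """Per-category contribution to one variable's marginal divergence.

    Splits the Jensen-Shannon divergence at a step into the additive
    contribution of each category of ``variable`` (each category's summand
    of the two Kullback-Leibler sums), ranked largest first.
    """
    from scipy.special import rel_entr

    if isinstance(location, (tuple, list)):
        m_a, m_b = to_month(location[0]), to_month(location[1])
    else:
        m_b = to_month(location)
        m_a = m_b - 1
    marg = marginalize(dtm, variable)
    p, q = marg.row(m_a), marg.row(m_b)
    m = 0.5 * (p + q)
    contrib = 0.5 * (rel_entr(p, m) + rel_entr(q, m)) / np.log(log_base)
    cats = [cell[0] for cell in marg.support]
    ranked = sorted(zip(cats, contrib.tolist()), key=lambda t: -t[1])
    return tuple(ranked)


def analyze(
    dtm: DataTemporalMap,
    k: float = 5.0,
    rho_threshold: float = 0.8,
    silhouette_threshold: float = 0.5,
    dims: int = 3,
    log_base: float = 2,
    groupings: Mapping[str, Sequence] | None = None,
) -> tuple[ChangeReport, dict]:
    """Run the full detection pipeline on a joint temporal map.

    Computes the pairwise matrices (divergence scale for the abrupt-change
    series and period clustering, where squaring sharpens the
    within/between contrast; distance scale for the embedding), runs all
    three detectors, and attributes every abrupt flag to its driving
    variables.  Returns the combined report plus the intermediate artifacts
    (``matrix_distance``, ``matrix_divergence``, ``series``,
    ``embedding``).
    """
    mat_div = pairwise_matrix(dtm, scale="divergence", log_base=log_base)
    mat_dist = mat_div.as_scale("distance")
    series = consecutive_series(mat_div)
    embedding = classical_mds(mat_dist, dims=min(dims, mat_dist.n_months - 1))

    flags: list[Flag] = []
    for f in detect_abrupt(series, k=k).flags:
        flags.append(
            Flag(f.kind, f.location, f.score, attribute_source(dtm, f.location, log_base))
        )
    if len(embedding.months) >= 12:
        flags.extend(detect_trend(embedding, rho_threshold=rho_threshold).flags)
    try:
        flags.extend(
            detect_period_clusters(
                mat_div, candidate_groupings=groupings,
                silhouette_threshold=silhouette_threshold,
            ).flags
        )
    except ValueError:
        pass  # too few groups (e.g. a window inside a single year)
    artifacts = {
        "matrix_distance": mat_dist,
        "matrix_divergence": mat_div,
        "series": series,
        "embedding": embedding,
    }
    return ChangeReport(tuple(flags)), artifacts
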