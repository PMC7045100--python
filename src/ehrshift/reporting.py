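"""Tabular and graphical summaries of temporal-variability analyses.

All quantitative exports are delimited text; images (data-temporal-map
heatmaps and information-geometric temporal scatter plots) are a thin
optional layer over the exported matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from ._months import to_month
from .igt import IGTEmbedding
from .temporal_map import DataTemporalMap, marginalize

__all__ = [
    "relative_change",
    "TrendSummary",
    "trend_summary",
    "dtm_heatmap",
    "igt_export",
    "load_igt",
]

_FLOAT_FMT = "%.17g"


def _round_half_away(x: Fraction, decimals: int) -> Fraction:
    scale = Fraction(10) ** decimals
    y = x * scale
    n, d = y.numerator, y.denominator
    q, r = divmod(abs(n), d)
    if 2 * r >= d:  # ties away from zero
        q += 1
    return Fraction(q if n >= 0 else -q, 1) / scale


def relative_change(start: float, end: float, decimals: int = 0) -> float:
    """Percent relative change ``100*(end-start)/start``, rounded.

    Inputs are interpreted exactly as the decimal numbers printed (via
    their shortest decimal representation), the change is evaluated in
    rational arithmetic, and the result rounded half-away-from-zero to
    ``decimals`` places -- so printed proportions reproduce printed
    percentages without binary-float artefacts.

    Raises for ``start <= 0`` (relative change is undefined at 0).
    """
    if start <= 0:
        raise ValueError("relative change is undefined for start <= 0")
    s = Fraction(repr(float(start)))
    e = Fraction(repr(float(end)))
    rc = 100 * (e - s) / s
    return float(_round_half_away(rc, decimals))


@dataclass(frozen=True)
class TrendSummary:
    """Start/end values and relative change of one category over a period."""

    variable: str
    category: object
    period: tuple
    start_value: float
    end_value: float
    relative_change_pct: float
    absolute_change: float


def trend_summary(
    dtm: DataTemporalMap, variable: str, category, period=None, decimals: int = 0
) -> TrendSummary:
    """Summarise one category's proportion trajectory over a period."""
    marg = marginalize(dtm, variable)
    months = marg.months
    if period is None:
        m_a, m_b = months[0], months[-1]
    else:
        m_a, m_b = to_month(period[0]), to_month(period[1])
    try:
        j = marg.support.index((category,))
    except ValueError:
        raise KeyError(f"category {category!r} not in variable {variable!r}") from None
    start_v = float(marg.row(m_a)[j])
    end_v = float(marg.row(m_b)[j])
    return TrendSummary(
        variable=variable,
        category=category,
        period=(m_a, m_b),
        start_value=start_v,
        end_value=end_v,
        relative_change_pct=relative_change(start_v, end_v, decimals=decimals),
        absolute_change=end_v - start_v,
    )


def dtm_heatmap(
    dtm: DataTemporalMap,
    path=None,
    image_path=None,
) -> pd.DataFrame:
    """Categories-by-months proportion matrix (the heatmap behind a DTM).

    Requires a single-variable (marginal) temporal map; marginalise a joint
    map first.  Rows are the variable's categories, columns the months,
    cells the proportion of the month's denominator in that category.  When
    ``path`` is given the matrix is written as CSV with month headers; when
    ``image_path`` is given a heatmap image is rendered from the same
    matrix.
    """
    if len(dtm.schema.variables) != 1:
        raise ValueError(
            "dtm_heatmap needs a single-variable map; use marginalize() on a joint map"
        )
    mat = pd.DataFrame(
        dtm.probabilities.T,
        index=[cell[0] for cell in dtm.support],
        columns=[str(m) for m in dtm.months],
    )
    mat.index.name = dtm.schema.variables[0]
    if path is not None:
        mat.to_csv(path, float_format=_FLOAT_FMT)
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, max(2, 0.3 * len(mat))))
        im = ax.imshow(mat.to_numpy(), aspect="auto", interpolation="nearest", cmap="viridis")
        ax.set_yticks(range(len(mat)), mat.index)
        step = max(1, len(mat.columns) // 15)
        ax.set_xticks(range(0, len(mat.columns), step), mat.columns[::step], rotation=90)
        fig.colorbar(im, ax=ax, label="proportion of monthly denominator")
        ax.set_xlabel("month")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return mat


def igt_export(embedding: IGTEmbedding, path=None, image_path=None) -> pd.DataFrame:
    """Export an embedding as one labelled record per month.

    Columns: month, glyph label and the embedding coordinates.  With
    ``path`` the table is written as CSV and the eigenvalue diagnostics
    (eigenvalues, variance explained, clamped negative mass) as a JSON
    sidecar next to it; with ``image_path`` a dims-1/2 trajectory plot is
    rendered.
    """
    df = embedding.to_frame().reset_index(names="month")
    df["month"] = df["month"].astype(str)
    if path is not None:
        path = Path(path)
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        sidecar = path.with_suffix(".diagnostics.json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "eigenvalues": embedding.eigenvalues.tolist(),
                    "variance_explained": embedding.variance_explained.tolist(),
                    "clamped_negative_mass": embedding.clamped_negative_mass,
                },
                fh,
                indent=1,
            )
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 6))
        xy = embedding.coordinates[:, :2]
        ax.plot(xy[:, 0], xy[:, 1], "-", color="0.8", zorder=1)
        ax.scatter(xy[:, 0], xy[:, 1], s=10, c=np.arange(len(xy)), cmap="viridis", zorder=2)
        for (x, y), lab in zip(xy, embedding.month_labels):
            ax.annotate(lab, (x, y), fontsize=6)
        ax.set_xlabel("dimension 1")
        ax.set_ylabel("dimension 2")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
    return df


def load_igt(path) -> IGTEmbedding:
    """Reload an embedding exported by :func:`igt_export`."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(".diagnostics.json")
    with open(sidecar) as fh:
        diag = json.load(fh)
    dim_cols = [c for c in df.columns if c.startswith("dim")]
    return IGTEmbedding(
        months=tuple(pd.Period(m, freq="M") for m in df["month"]),
        coordinates=df[dim_cols].to_numpy(dtype=float),
        eigenvalues=np.asarray(diag["eigenvalues"], dtype=float),
        variance_explained=np.asarray(diag["variance_explained"], dtype=float),
        month_labels=tuple(df["label"]),
        clamped_negative_mass=float(diag["clamped_negative_mass"]),
    )
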