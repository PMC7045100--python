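"""Monthly cross-sectional slicing of longitudinal health records.

Longitudinal primary-care records (a patient table plus a dated event
table) or preaggregated hospital count tables are converted into one
cross-section per calendar month.  For primary care a patient contributes
to month *m* when, on the first day of *m*, they are inside the eligible
age range and have been registered with their practice for at least one
year; a condition flag is 1 when any code from the condition's codelist was
recorded strictly before the first day of *m* (ever-recorded phenotype).
Patients who deregister during a month still contribute to that month.

Because the patient table carries only the year of birth, age is by default
incremented each July: everyone born in year *y* is treated as turning
``year - y`` years old on 1 July.  This reproduces the artificial yearly
July jump familiar from year-of-birth-only databases; an exact
date-of-birth mode is available when a ``date_of_birth`` column exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._months import month_range, to_month

__all__ = [
    "Codelist",
    "VariableSchema",
    "MonthlySlice",
    "compute_age_band",
    "build_primary_care_slices",
    "build_hospital_slices",
    "PRIMARY_CARE_AGE_BANDS",
    "HOSPITAL_AGE_BANDS",
]

#: inclusive lower band edges used in the primary-care analysis
PRIMARY_CARE_AGE_BANDS: tuple[int, ...] = (20, 40, 60, 80)
#: inclusive lower band edges used in the hospital analysis
HOSPITAL_AGE_BANDS: tuple[int, ...] = (40, 45, 50, 55, 60, 65, 70, 75)

_TERMINOLOGIES = ("read", "icd10-3char")


@dataclass(frozen=True)
class Codelist:
    """A named set of clinical codes defining one condition."""

    condition: str
    codes: frozenset[str]
    terminology: str = "read"

    def __post_init__(self):
        object.__setattr__(self, "codes", frozenset(self.codes))
        if not self.codes:
            raise ValueError(f"codelist {self.condition!r} is empty")
        if self.terminology not in _TERMINOLOGIES:
            raise ValueError(
                f"unknown terminology {self.terminology!r}; expected one of {_TERMINOLOGIES}"
            )

    def normalize(self, codes: pd.Series) -> pd.Series:
        """Normalise raw codes for matching (3-character truncation for ICD-10)."""
        codes = codes.astype(str).str.strip()
        if self.terminology == "icd10-3char":
            codes = codes.str[:3]
        return codes


def validate_codelists(codelists: Sequence[Codelist]) -> None:
    """Reject codelist sets where one code maps to two conditions."""
    seen: dict[str, str] = {}
    for cl in codelists:
        for code in cl.codes:
            if code in seen and seen[code] != cl.condition:
                raise ValueError(
                    f"code {code!r} appears in both {seen[code]!r} and {cl.condition!r}"
                )
            seen[code] = cl.condition


@dataclass(frozen=True)
class VariableSchema:
    """Ordered variable names with their category sets."""

    variables: tuple[str, ...]
    categories: Mapping[str, tuple]

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(
            self, "categories", {v: tuple(c) for v, c in self.categories.items()}
        )
        missing = [v for v in self.variables if v not in self.categories]
        if missing:
            raise ValueError(f"no categories declared for variables {missing}")

    def sort_key(self, cell: tuple):
        """Lexicographic key by variable order then declared category order."""
        return tuple(self.categories[v].index(c) for v, c in zip(self.variables, cell))

    def subset(self, variables: Sequence[str]) -> "VariableSchema":
        unknown = [v for v in variables if v not in self.variables]
        if unknown:
            raise KeyError(f"unknown variables {unknown}")
        return VariableSchema(tuple(variables), {v: self.categories[v] for v in variables})


@dataclass(frozen=True)
class MonthlySlice:
    """One month's cross-sectional cell counts.

    ``counts`` maps a tuple of category values (one per schema variable) to a
    non-negative integer; ``denominator`` is the month's total and always
    equals the sum of the counts.
    """

    month: pd.Period
    counts: Mapping[tuple, int]
    denominator: int
    schema: VariableSchema

    def __post_init__(self):
        object.__setattr__(self, "month", to_month(self.month))
        counts = {tuple(k): int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in counts.values()):
            raise ValueError("negative cell count")
        for cell in counts:
            if len(cell) != len(self.schema.variables):
                raise ValueError(f"cell {cell} does not match schema arity")
            for var, cat in zip(self.schema.variables, cell):
                if cat not in self.schema.categories[var]:
                    raise ValueError(f"unknown category {cat!r} for variable {var!r}")
        total = sum(counts.values())
        if total != self.denominator:
            raise ValueError(
                f"denominator {self.denominator} != sum of counts {total} in {self.month}"
            )
        object.__setattr__(self, "counts", counts)

    @property
    def is_empty(self) -> bool:
        return self.denominator == 0


def _band_labels(band_edges: Sequence[int]) -> list[str]:
    edges = list(band_edges)
    labels = []
    for lo, hi in zip(edges, edges[1:]):
        labels.append(f"{lo}-{hi - 1}")
    labels.append(f"{edges[-1]}+")
    return labels


def age_band_labels(band_edges: Sequence[int]) -> list[str]:
    """Public labels for a set of inclusive lower band edges."""
    return _band_labels(band_edges)


def compute_age(year_of_birth: int, month) -> int:
    """Age under the July convention for year-of-birth-only data."""
    m = to_month(month)
    age = m.year - int(year_of_birth) - (0 if m.month >= 7 else 1)
    return age


def compute_age_band(year_of_birth: int, month, band_edges: Sequence[int]) -> str:
    """Age band for a year of birth at a given month.

    Age increments in July (see module docstring); bands are assigned by
    inclusive lower edges.  Raises for negative ages or births outside a
    plausible 1880-2015 window.
    """
    yob = int(year_of_birth)
    if not 1880 <= yob <= 2015:
        raise ValueError(f"implausible year of birth {yob}")
    age = compute_age(yob, month)
    if age < 0:
        raise ValueError(f"negative age for year of birth {yob} at {month}")
    edges = list(band_edges)
    if age < edges[0]:
        raise ValueError(f"age {age} below the lowest band edge {edges[0]}")
    labels = _band_labels(edges)
    idx = int(np.searchsorted(edges, age, side="right")) - 1
    return labels[idx]


def _ages_vector(yob: np.ndarray, month: pd.Period) -> np.ndarray:
    return month.year - yob - (0 if month.month >= 7 else 1)


def build_primary_care_slices(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    codelists: Sequence[Codelist],
    months,
    age_range: tuple[int, int] = (20, 110),
    min_registration_days: int = 365,
    age_bands: Sequence[int] = PRIMARY_CARE_AGE_BANDS,
    genders: Sequence[str] = ("F", "M"),
) -> list[MonthlySlice]:
    """Monthly cross-sections of a primary-care cohort.

    Parameters
    ----------
    patients
        Columns ``patient_id``, ``year_of_birth``, ``gender``,
        ``imd_quintile``, ``registration_start``, ``registration_end``
        (missing/empty end = still registered).
    events
        Columns ``patient_id``, ``event_date``, ``code``.
    codelists
        One :class:`Codelist` per condition; each yields a binary
        ever-recorded flag variable named after the condition.
    months
        Iterable of contiguous calendar months (or anything month-parsable).
    age_range
        Inclusive eligible age interval on the first of the month.
    min_registration_days
        Registration must have started at least this many days before the
        first of the month ("registered for at least 1 year" = 365).

    Returns
    -------
    list of :class:`MonthlySlice`
        One per requested month.  Months with no eligible patients are
        returned as explicit empty slices with a warning.
    """
    months = [to_month(m) for m in months]
    validate_codelists(codelists)
    for cl in codelists:
        if cl.terminology not in _TERMINOLOGIES:  # pragma: no cover - Codelist validates
            raise ValueError(f"unknown terminology {cl.terminology!r}")

    pat = patients.copy()
    # complete-record requirement on age, gender and deprivation
    complete = pat[["year_of_birth", "gender", "imd_quintile"]].notna().all(axis=1)
    pat = pat[complete]
    yob = pat["year_of_birth"].to_numpy(dtype=int)
    gender = pat["gender"].astype(str).to_numpy()
    imd = pat["imd_quintile"].to_numpy(dtype=int)
    reg_start = pd.to_datetime(pat["registration_start"]).to_numpy(dtype="datetime64[D]")
    reg_end_raw = pd.to_datetime(pat.get("registration_end"), errors="coerce")
    reg_end = reg_end_raw.to_numpy(dtype="datetime64[D]")
    open_end = reg_end_raw.isna().to_numpy()

    pid = pat["patient_id"].to_numpy()
    pid_index = pd.Index(pid)

    # first qualifying event date per patient per condition
    ev_dates = pd.to_datetime(events["event_date"])
    first_dates = np.full((len(codelists), len(pat)), np.datetime64("NaT"), dtype="datetime64[D]")
    for ci, cl in enumerate(codelists):
        codes = cl.normalize(events["code"])
        sel = codes.isin(cl.codes)
        if not sel.any():
            continue
        firsts = ev_dates[sel].groupby(events.loc[sel, "patient_id"]).min()
        pos = pid_index.get_indexer(firsts.index)
        ok = pos >= 0
        first_dates[ci, pos[ok]] = firsts.to_numpy(dtype="datetime64[D]")[ok]

    band_labels = _band_labels(age_bands)
    edges = np.asarray(age_bands)
    cond_names = tuple(cl.condition for cl in codelists)
    schema = VariableSchema(
        ("age_band", "gender", "imd_quintile") + cond_names,
        {
            "age_band": tuple(band_labels),
            "gender": tuple(genders),
            "imd_quintile": (1, 2, 3, 4, 5),
            **{c: (0, 1) for c in cond_names},
        },
    )

    slices: list[MonthlySlice] = []
    for m in months:
        first = np.datetime64(m.start_time.date(), "D")
        ages = _ages_vector(yob, m)
        eligible = (
            (ages >= age_range[0])
            & (ages <= age_range[1])
            & (reg_start <= first - np.timedelta64(min_registration_days, "D"))
            & (open_end | (reg_end >= first))
        )
        if not eligible.any():
            warnings.warn(f"month {m} has no eligible patients; kept as an empty slice")
            slices.append(MonthlySlice(m, {}, 0, schema))
            continue
        idx = np.flatnonzero(eligible)
        band_idx = np.searchsorted(edges, ages[idx], side="right") - 1
        cols = {
            "age_band": np.asarray(band_labels, dtype=object)[band_idx],
            "gender": gender[idx],
            "imd_quintile": imd[idx],
        }
        for ci, name in enumerate(cond_names):
            fd = first_dates[ci, idx]
            cols[name] = ((~np.isnat(fd)) & (fd < first)).astype(int)
        df = pd.DataFrame(cols)
        counts = df.groupby(list(schema.variables), sort=False, observed=True).size()
        slices.append(
            MonthlySlice(m, dict(counts.items()), int(counts.sum()), schema)
        )
    return slices


def build_hospital_slices(
    count_table: pd.DataFrame,
    codelist: Codelist,
    months,
    age_bands: Sequence[int] = HOSPITAL_AGE_BANDS,
    genders: Sequence[str] = ("F", "M"),
) -> list[MonthlySlice]:
    """Monthly cross-sections from a preaggregated hospital count table.

    ``count_table`` needs columns ``month``, ``age_band``, ``gender``,
    ``imd_quintile``, ``code``, ``count``.  Codes are truncated to 3
    characters (ICD-10 convention) and those outside ``codelist`` are
    dropped *before* the monthly denominator is formed.
    """
    months = [to_month(m) for m in months]
    df = count_table.copy()
    if (df["count"] < 0).any():
        raise ValueError("negative counts in the hospital count table")
    expected_bands = set(_band_labels(age_bands))
    bad = set(df["age_band"].astype(str).unique()) - expected_bands
    if bad:
        raise ValueError(f"unknown age band labels {sorted(bad)}; expected {sorted(expected_bands)}")

    df["code"] = codelist.normalize(df["code"])
    df = df[df["code"].isin(codelist.codes)]
    df["month"] = pd.PeriodIndex(df["month"].astype(str), freq="M")

    code_support = tuple(sorted(codelist.codes))
    schema = VariableSchema(
        ("age_band", "gender", "imd_quintile", "code"),
        {
            "age_band": tuple(_band_labels(age_bands)),
            "gender": tuple(genders),
            "imd_quintile": (1, 2, 3, 4, 5),
            "code": code_support,
        },
    )

    grouped = df.groupby(["month", "age_band", "gender", "imd_quintile", "code"], observed=True)[
        "count"
    ].sum()

    slices: list[MonthlySlice] = []
    for m in months:
        try:
            month_counts = grouped.xs(m, level="month")
        except KeyError:
            month_counts = pd.Series(dtype=int)
        cells = {
            (ab, g, int(q), c): int(v)
            for (ab, g, q, c), v in month_counts.items()
            if v > 0
        }
        denom = sum(cells.values())
        if denom == 0:
            warnings.warn(f"month {m} has no included codes; kept as an empty slice")
        slices.append(MonthlySlice(m, cells, denom, schema))
    return slices
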