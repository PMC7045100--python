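"""Delimited-text serialization of the pipeline's intermediate objects.

Everything round-trips through plain CSV (RFC-4180 via pandas) plus small
JSON sidecars for schema/metadata, so each pipeline stage can run as a
separate process on files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dissimilarity import DissimilarityMatrix
from .slicing import MonthlySlice, VariableSchema
from .temporal_map import DataTemporalMap

__all__ = [
    "write_slices", "read_slices",
    "write_dtm", "read_dtm",
    "write_matrix", "read_matrix",
]

_FLOAT_FMT = "%.17g"


def _schema_to_dict(schema: VariableSchema) -> dict:
    return {"variables": list(schema.variables),
            "categories": {v: list(c) for v, c in schema.categories.items()}}


def _schema_from_dict(d: dict) -> VariableSchema:
    return VariableSchema(tuple(d["variables"]),
                          {v: tuple(c) for v, c in d["categories"].items()})


def write_slices(slices: list[MonthlySlice], path) -> None:
    """Long-format CSV (month, variables..., count) plus a schema sidecar."""
    path = Path(path)
    schema = slices[0].schema
    rows = []
    for s in slices:
        for cell, v in s.counts.items():
            rows.append((str(s.month), *cell, v))
    df = pd.DataFrame(rows, columns=["month", *schema.variables, "count"])
    df.to_csv(path, index=False)
    with open(path.with_suffix(".schema.json"), "w") as fh:
        json.dump({"schema": _schema_to_dict(schema),
                   "months": [str(s.month) for s in slices]}, fh, indent=1)


def read_slices(path) -> list[MonthlySlice]:
    path = Path(path)
    with open(path.with_suffix(".schema.json")) as fh:
        meta = json.load(fh)
    schema = _schema_from_dict(meta["schema"])
    df = pd.read_csv(path)
    # restore category dtypes from the schema (ints read back as ints already)
    by_month: dict[str, dict] = {str(m): {} for m in meta["months"]}
    for row in df.itertuples(index=False):
        month = str(row.month)
        cell = tuple(getattr(row, v) for v in schema.variables)
        by_month.setdefault(month, {})[cell] = int(row.count)
    return [
        MonthlySlice(pd.Period(m, freq="M"), cells, sum(cells.values()), schema)
        for m, cells in by_month.items()
    ]


def write_dtm(dtm: DataTemporalMap, path) -> None:
    """Months-by-support counts CSV plus a schema sidecar."""
    path = Path(path)
    df = dtm.to_frame(kind="counts")
    df.index = df.index.astype(str)
    df.index.name = "month"
    df.to_csv(path)
    with open(path.with_suffix(".schema.json"), "w") as fh:
        json.dump({"schema": _schema_to_dict(dtm.schema),
                   "support": [list(c) for c in dtm.support]}, fh, indent=1)


def read_dtm(path) -> DataTemporalMap:
    path = Path(path)
    with open(path.with_suffix(".schema.json")) as fh:
        meta = json.load(fh)
    schema = _schema_from_dict(meta["schema"])
    df = pd.read_csv(path, index_col="month")
    support = tuple(tuple(c) for c in meta["support"])
    # JSON stringifies nothing here but CSV loses tuple types; rebuild from sidecar
    return DataTemporalMap(
        months=tuple(pd.Period(m, freq="M") for m in df.index),
        support=support,
        counts=df.to_numpy(dtype=np.int64),
        schema=schema,
    )


def write_matrix(matrix: DissimilarityMatrix, path) -> None:
    path = Path(path)
    df = matrix.to_frame()
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "month"
    df.to_csv(path, float_format=_FLOAT_FMT)
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump({"scale": matrix.scale, "log_base": matrix.log_base}, fh)


def read_matrix(path) -> DissimilarityMatrix:
    path = Path(path)
    with open(path.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    df = pd.read_csv(path, index_col="month", float_precision="round_trip")
    return DissimilarityMatrix(
        months=tuple(pd.Period(m, freq="M") for m in df.index),
        values=df.to_numpy(dtype=float),
        scale=meta["scale"],
        log_base=meta["log_base"],
    )
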