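import numpy as np
import pandas as pd
import pytest

from ehrshift.slicing import MonthlySlice, VariableSchema


@pytest.fixture
def binary_schema():
    return VariableSchema(
        ("gender", "hf"), {"gender": ("F", "M"), "hf": (0, 1)}
    )


def make_slice(month, cells, schema):
    return MonthlySlice(month, cells, sum(cells.values()), schema)


@pytest.fixture
def toy_slices(binary_schema):
    """Three months over a gender x heart-failure-flag joint."""
    return [
        make_slice("2001-01", {("M", 1): 10, ("M", 0): 40, ("F", 1): 5, ("F", 0): 45}, binary_schema),
        make_slice("2001-02", {("M", 1): 12, ("M", 0): 38, ("F", 1): 6, ("F", 0): 44}, binary_schema),
        make_slice("2001-03", {("M", 1): 20, ("M", 0): 30, ("F", 1): 10, ("F", 0): 40}, binary_schema),
    ]


def dirichlet_vectors(rng, n, dim, alpha=1.0):
    return rng.dirichlet(np.full(dim, alpha), size=n)
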