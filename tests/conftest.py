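import numpy as np
import pandas as pd
import pytest

from cuvarp.tables_io import ColumnSpec, SampleTable, VariableSchema


def quant_table(values, ids=None, columns=None) -> SampleTable:
    """Build an all-quantitative SampleTable from an array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"s{i+1}" for i in range(values.shape[0])]
    columns = columns or [f"v{j+1}" for j in range(values.shape[1])]
    return SampleTable.from_numeric(pd.DataFrame(values, index=ids, columns=columns))


def mixed_table() -> SampleTable:
    """Small mixed-type table exercising every variable kind."""
    schema = VariableSchema(
        [
            ColumnSpec("q", "quantitative"),
            ColumnSpec("o", "ordinal", (0, 1, 2, 3)),
            ColumnSpec("f", "factor", ("A", "B", "C")),
            ColumnSpec("b", "binary"),
        ]
    )
    data = pd.DataFrame(
        {
            "q": [0.0, 5.0, 10.0, 2.5],
            "o": [0, 1, 3, 2],
            "f": ["A", "A", "B", "C"],
            "b": [0, 1, 1, 0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return SampleTable(data, schema)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
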