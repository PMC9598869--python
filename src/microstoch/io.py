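"""Count-table I/O: plain TSV with taxa as rows and samples as columns.

The on-disk dialect is the field's usual OTU-table layout: first column
``taxon_id``, one integer column per sample. In memory the package works
with the transpose (samples as rows). Round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .community import InvalidInputError, validate_count_matrix

__all__ = ["read_count_table", "write_count_table"]


def write_count_table(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a sample x taxon matrix as a taxon-rows TSV count table."""
    validate_count_matrix(matrix, require_positive_rows=False)
    table = matrix.T
    table.index = table.index.rename("taxon_id")  # leave the input untouched
    table.to_csv(path, sep="\t")


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a taxon-rows TSV count table into a sample x taxon matrix.

    Malformed cells (negative, non-integer, non-numeric) are rejected with
    the offending taxon and sample named.
    """
    table = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if table.index.name != "taxon_id":
        raise InvalidInputError(
            f"{path}: first column must be named 'taxon_id', got {table.index.name!r}"
        )
    numeric = table.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise InvalidInputError(
            f"{path}: non-numeric count at taxon {table.index[i]!r}, "
            f"sample {table.columns[j]!r}"
        )
    values = numeric.to_numpy()
    bad = np.argwhere(values != np.floor(values))
    if bad.size:
        i, j = bad[0]
        raise InvalidInputError(
            f"{path}: non-integer count at taxon {table.index[i]!r}, "
            f"sample {table.columns[j]!r}"
        )
    bad = np.argwhere(values < 0)
    if bad.size:
        i, j = bad[0]
        raise InvalidInputError(
            f"{path}: negative count at taxon {table.index[i]!r}, "
            f"sample {table.columns[j]!r}"
        )
    matrix = pd.DataFrame(
        values.astype(np.int64).T,
        index=[str(c) for c in table.columns],
        columns=[str(t) for t in table.index],
    )
    validate_count_matrix(matrix, require_positive_rows=False)
    return matrix
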