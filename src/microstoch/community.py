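"""Core data containers: single communities and sample x taxon count tables.

A :class:`Community` is one sample's taxon -> abundance map (individuals,
non-negative integers). A *count matrix* is the package's universal currency
for metacommunities: a :class:`pandas.DataFrame` with samples as rows and
taxa as columns, integer cells, validated by :func:`validate_count_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Community",
    "validate_count_matrix",
    "matrix_from_communities",
]


class InvalidParameterError(ValueError):
    """A parameter violates an operation's preconditions."""


class InvalidInputError(ValueError):
    """Input data violate a structural contract (ids, universes, totals)."""


class InsufficientDataError(ValueError):
    """Too little data to compute the requested quantity."""


@dataclass(frozen=True)
class Community:
    """One sample: ordered taxon identifiers with aligned integer abundances.

    Invariants (enforced at construction): unique taxon ids, abundances
    non-negative integers, same length as ids.
    """

    taxon_ids: tuple[str, ...]
    abundances: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances)
        if ab.ndim != 1 or len(self.taxon_ids) != ab.shape[0]:
            raise InvalidInputError(
                "taxon_ids and abundances must be 1-D and aligned"
            )
        if not np.issubdtype(ab.dtype, np.integer):
            if not np.all(ab == np.floor(ab)):
                raise InvalidInputError("abundances must be integers")
            ab = ab.astype(np.int64)
        if np.any(ab < 0):
            raise InvalidInputError("abundances must be non-negative")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise InvalidInputError("taxon_ids must be unique")
        object.__setattr__(self, "taxon_ids", tuple(str(t) for t in self.taxon_ids))
        object.__setattr__(self, "abundances", ab.astype(np.int64))

    @property
    def total(self) -> int:
        """Total number of individuals."""
        return int(self.abundances.sum())

    @property
    def richness(self) -> int:
        """Number of taxa with at least one individual."""
        return int(np.count_nonzero(self.abundances))

    def to_series(self) -> pd.Series:
        return pd.Series(self.abundances, index=list(self.taxon_ids), dtype=np.int64)

    @classmethod
    def from_series(cls, s: pd.Series) -> "Community":
        return cls(tuple(str(i) for i in s.index), s.to_numpy())


def validate_count_matrix(matrix: pd.DataFrame, require_positive_rows: bool = True) -> None:
    """Check the count-matrix contract: unique ids, integer non-negative cells.

    Raises :class:`InvalidInputError` naming the first offending cell.
    """
    if matrix.index.has_duplicates:
        raise InvalidInputError("duplicate sample ids in count matrix")
    if matrix.columns.has_duplicates:
        raise InvalidInputError("duplicate taxon ids in count matrix")
    values = matrix.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        bad = np.argwhere(values != np.floor(values))
        if bad.size:
            i, j = bad[0]
            raise InvalidInputError(
                f"non-integer count at sample {matrix.index[i]!r}, "
                f"taxon {matrix.columns[j]!r}"
            )
    bad = np.argwhere(values < 0)
    if bad.size:
        i, j = bad[0]
        raise InvalidInputError(
            f"negative count at sample {matrix.index[i]!r}, taxon {matrix.columns[j]!r}"
        )
    if require_positive_rows:
        totals = values.sum(axis=1)
        if np.any(totals <= 0):
            empty = matrix.index[np.asarray(totals <= 0)].tolist()
            raise InvalidInputError(f"samples with zero total: {empty}")


def matrix_from_communities(
    communities: dict[str, Community] | list[Community],
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble a sample x taxon count matrix over the union of taxon ids.

    Taxa absent from a sample are filled with 0. Column order is the order
    of first appearance across samples (deterministic).
    """
    if isinstance(communities, dict):
        items = list(communities.items())
    else:
        ids = sample_ids or [f"S{i:02d}" for i in range(len(communities))]
        items = list(zip(ids, communities))
    union: dict[str, None] = {}
    for _, com in items:
        for t in com.taxon_ids:
            union.setdefault(t, None)
    columns = list(union)
    col_pos = {t: j for j, t in enumerate(columns)}
    out = np.zeros((len(items), len(columns)), dtype=np.int64)
    for i, (_, com) in enumerate(items):
        idx = np.fromiter((col_pos[t] for t in com.taxon_ids), dtype=np.int64)
        out[i, idx] = com.abundances
    return pd.DataFrame(out, index=[sid for sid, _ in items], columns=columns)
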