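"""Bray-Curtis beta-diversity and the abundant/rare partition.

Beta-diversity is pairwise Bray-Curtis dissimilarity on raw count vectors:
``1 - 2 * sum(min(x, y)) / (sum(x) + sum(y))``. The abundant subcommunity is
the minimal set of top-ranked taxa reaching a cumulative relative-abundance
threshold (80% by default); everything else is rare. Subcommunity
beta-diversity restricts columns to the subset without renormalising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import InvalidInputError, InvalidParameterError, validate_count_matrix

__all__ = [
    "bray_curtis",
    "pairwise_beta",
    "partition_abundant_rare",
    "SubcommunityPartition",
    "BetaResult",
]

logger = logging.getLogger(__name__)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray-Curtis dissimilarity between two aligned abundance vectors.

    0 means identical composition, 1 means no shared taxa. Undefined (and
    an error) when both vectors are all-zero.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InvalidInputError("vectors must be aligned on the same taxa")
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidInputError("abundances must be non-negative")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise InvalidInputError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


@dataclass(frozen=True)
class BetaResult:
    """All pairwise Bray-Curtis values of a count matrix, plus their mean.

    ``pairs`` is indexed by (sample_i, sample_j) with i < j in matrix order;
    pairs excluded because a member had zero total within the analysed
    taxon subset are listed in ``excluded``.
    """

    pairs: pd.Series
    mean: float
    excluded: tuple[tuple[str, str], ...] = ()


def _pairwise_bc_condensed(values: np.ndarray) -> np.ndarray:
    """Condensed (upper-triangle) Bray-Curtis distances, vectorised.

    Equivalent to scipy's ``pdist(values, "braycurtis")`` for non-negative
    input but tolerant of zero-total rows (returns NaN for those pairs).
    """
    v = values.astype(np.float64, copy=False)
    totals = v.sum(axis=1)
    n = v.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=np.float64)
    k = 0
    for i in range(n - 1):
        shared = np.minimum(v[i], v[i + 1 :]).sum(axis=1)
        denom = totals[i] + totals[i + 1 :]
        with np.errstate(divide="ignore", invalid="ignore"):
            out[k : k + n - 1 - i] = 1.0 - 2.0 * shared / denom
        k += n - 1 - i
    return out


def pairwise_beta(matrix: pd.DataFrame, subset: set[str] | None = None) -> BetaResult:
    """All n(n-1)/2 pairwise Bray-Curtis dissimilarities and their mean.

    With ``subset``, columns are restricted to those taxa first (raw counts,
    no renormalisation). Pairs involving a sample whose subset total is zero
    are excluded with a warning rather than reported as NaN.
    """
    validate_count_matrix(matrix, require_positive_rows=False)
    sub = matrix if subset is None else matrix.loc[:, matrix.columns.isin(set(subset))]
    values = sub.to_numpy()
    condensed = _pairwise_bc_condensed(values)
    # a pair is undefined when either member has nothing in the analysed taxa
    empty = values.sum(axis=1) == 0
    if empty.any():
        n_rows = values.shape[0]
        k = 0
        for i in range(n_rows - 1):
            for j in range(i + 1, n_rows):
                if empty[i] or empty[j]:
                    condensed[k] = np.nan
                k += 1
    sample_ids = list(matrix.index)
    n = len(sample_ids)
    index = pd.MultiIndex.from_tuples(
        [(sample_ids[i], sample_ids[j]) for i in range(n) for j in range(i + 1, n)],
        names=["sample_i", "sample_j"],
    )
    pairs = pd.Series(condensed, index=index, name="bray_curtis")
    bad = pairs.index[np.isnan(pairs.to_numpy())]
    if len(bad):
        logger.warning(
            "excluding %d sample pair(s) with zero subset totals: %s",
            len(bad), list(bad[:5]),
        )
        pairs = pairs.dropna()
    if pairs.empty:
        raise InvalidInputError("no valid sample pairs to compute beta-diversity")
    return BetaResult(pairs=pairs, mean=float(pairs.mean()), excluded=tuple(bad))


@dataclass(frozen=True)
class SubcommunityPartition:
    """Disjoint abundant/rare split of the taxa of one count matrix."""

    abundant_taxa: frozenset
    rare_taxa: frozenset
    threshold: float

    @property
    def abundant_richness_share(self) -> float:
        total = len(self.abundant_taxa) + len(self.rare_taxa)
        return len(self.abundant_taxa) / total if total else 0.0


def partition_abundant_rare(
    matrix: pd.DataFrame, threshold: float = 0.80
) -> SubcommunityPartition:
    """Split taxa into abundant and rare by cumulative relative abundance.

    Taxa are ranked by total count over all samples (descending; ties by
    taxon id ascending for determinism). The abundant set is the shortest
    prefix whose cumulative share of the grand total reaches ``threshold``;
    all remaining taxa with positive totals are rare. All-zero taxa belong
    to neither set.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidParameterError(f"threshold must be in (0, 1), got {threshold}")
    validate_count_matrix(matrix, require_positive_rows=False)
    totals = matrix.sum(axis=0)
    totals = totals[totals > 0]
    if totals.empty:
        raise InvalidInputError("matrix has zero grand total")
    ranked = totals.sort_index(ascending=True).sort_values(ascending=False, kind="stable")
    cumshare = ranked.cumsum() / ranked.sum()
    # shortest prefix reaching the threshold; 1e-12 absorbs float noise in the cumsum
    n_abundant = int(np.searchsorted(cumshare.to_numpy(), threshold - 1e-12) + 1)
    n_abundant = min(n_abundant, len(ranked))
    abundant = frozenset(ranked.index[:n_abundant])
    rare = frozenset(ranked.index[n_abundant:])
    return SubcommunityPartition(abundant, rare, threshold)
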