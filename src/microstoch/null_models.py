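"""Null-community randomization under fixed richness and regional constraints.

Two randomization schemes generate ensembles of null count matrices from an
observed one, both holding each sample's richness and total fixed and
choosing which taxa are occupied by weighted sampling without replacement
from the regional pool, with weights equal to occurrence frequency:

* **shuffle** — each sample's observed multiset of abundance values is
  reassigned to the chosen taxa by a uniform random permutation; expected to
  yield highly *dissimilar* null communities.
* **proportional** — each occupied taxon gets one individual, then the rest
  of the sample's total is allocated by a multinomial draw proportional to
  regional relative abundances; expected to yield *similar* null communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd

from ._rng import spawn_seed, substream
from .community import InvalidInputError, InvalidParameterError, validate_count_matrix
from .diversity import _pairwise_bc_condensed

__all__ = [
    "RegionalPool",
    "NullEnsemble",
    "build_regional_pool",
    "randomize_shuffle",
    "randomize_proportional",
    "generate_ensemble",
]

NullMethod = Literal["shuffle", "proportional"]


@dataclass(frozen=True)
class RegionalPool:
    """The regional species pool of a metacommunity at one depth.

    ``occurrence_frequency[t]`` counts the samples where taxon ``t`` has a
    positive count; ``regional_relative_abundance[t]`` is its share of the
    pooled counts. Taxa absent everywhere are excluded.
    """

    taxon_ids: tuple[str, ...]
    occurrence_frequency: np.ndarray = field(repr=False)
    regional_relative_abundance: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.taxon_ids)


def build_regional_pool(matrix: pd.DataFrame) -> RegionalPool:
    """Occurrence frequencies and pooled relative abundances over all samples."""
    validate_count_matrix(matrix, require_positive_rows=False)
    pooled = matrix.sum(axis=0).to_numpy()
    present = pooled > 0
    freq = (matrix.to_numpy() > 0).sum(axis=0)[present].astype(np.float64)
    rel = pooled[present].astype(np.float64)
    rel /= rel.sum()
    ids = tuple(str(t) for t in matrix.columns[present])
    return RegionalPool(ids, freq, rel)


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of k items drawn successively without replacement, P ∝ weight.

    Uses the exponential-race formulation: item i wins with key
    Exp(1)/w_i, and the k smallest keys have exactly the law of successive
    weighted draws without replacement.
    """
    if k == len(weights):
        return np.arange(k)
    keys = rng.exponential(size=len(weights)) / weights
    return np.argpartition(keys, k)[:k]


def _occupancy(
    row: np.ndarray, pool: RegionalPool, pool_index: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Choose occupied taxa (columns of the observed matrix) for one sample."""
    positive = np.flatnonzero(row > 0)
    k = positive.size
    if k > pool.size:
        raise InvalidInputError(
            f"sample richness {k} exceeds regional pool size {pool.size}"
        )
    if k == 0:
        return positive, np.empty(0, dtype=np.int64)
    chosen = _weighted_sample_without_replacement(pool.occurrence_frequency, k, rng)
    return positive, pool_index[chosen]


def _pool_column_index(matrix: pd.DataFrame, pool: RegionalPool) -> np.ndarray:
    col_pos = {t: j for j, t in enumerate(map(str, matrix.columns))}
    try:
        return np.fromiter((col_pos[t] for t in pool.taxon_ids), dtype=np.int64)
    except KeyError as err:
        raise InvalidInputError(f"pool taxon {err} missing from matrix columns") from err


def randomize_shuffle(
    matrix: pd.DataFrame, pool: RegionalPool, rng_seed: int = 0
) -> pd.DataFrame:
    """One null matrix: frequency-weighted occupancy, permuted abundances.

    Per sample: occupied taxa are drawn without replacement with weights
    equal to regional occurrence frequency, exactly as many as the observed
    richness; the sample's observed positive abundance values are then
    assigned to them in uniformly random order. Richness, totals and each
    sample's abundance multiset are conserved exactly. Empty samples stay
    empty.
    """
    validate_count_matrix(matrix, require_positive_rows=False)
    values = matrix.to_numpy()
    pool_index = _pool_column_index(matrix, pool)
    out = np.zeros_like(values)
    for i in range(values.shape[0]):
        rng = substream(rng_seed, "shuffle", i)
        positive, target = _occupancy(values[i], pool, pool_index, rng)
        abundances = values[i, positive]
        out[i, target] = rng.permutation(abundances)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def randomize_proportional(
    matrix: pd.DataFrame, pool: RegionalPool, rng_seed: int = 0
) -> pd.DataFrame:
    """One null matrix: frequency-weighted occupancy, region-proportional fill.

    Per sample: occupancy as in :func:`randomize_shuffle`; every occupied
    taxon receives a floor of one individual (so the fixed-richness
    constraint holds exactly), and the remaining ``total - richness``
    individuals are allocated by one multinomial draw with probabilities
    proportional to the occupied taxa's regional relative abundances.
    """
    validate_count_matrix(matrix, require_positive_rows=False)
    values = matrix.to_numpy()
    pool_index = _pool_column_index(matrix, pool)
    pos_of_pool = np.full(values.shape[1], -1, dtype=np.int64)
    pos_of_pool[pool_index] = np.arange(pool.size)
    out = np.zeros_like(values)
    for i in range(values.shape[0]):
        rng = substream(rng_seed, "proportional", i)
        positive, target = _occupancy(values[i], pool, pool_index, rng)
        total = int(values[i].sum())
        k = positive.size
        if k == 0:
            continue
        if total < k:
            raise InvalidInputError(
                f"sample total {total} smaller than its richness {k}"
            )
        p = pool.regional_relative_abundance[pos_of_pool[target]]
        p = p / p.sum()
        counts = np.ones(k, dtype=np.int64)
        if total > k:
            counts += rng.multinomial(total - k, p)
        out[i, target] = counts
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


_RANDOMIZERS = {"shuffle": randomize_shuffle, "proportional": randomize_proportional}


@dataclass
class NullEnsemble:
    """A reproducible stream of null matrices plus cached null dissimilarities.

    Holds provenance (source matrix, method, iteration count, seed) rather
    than the matrices themselves: matrices are regenerated on demand from
    the seed, which is exact by the determinism contract, and only the
    pairwise Bray-Curtis values per requested taxon subset are cached
    (memory bounded by iterations x n_pairs per subset).
    """

    matrix: pd.DataFrame
    method: NullMethod
    iterations: int
    rng_seed: int
    _null_bc: dict[frozenset | None, np.ndarray] = field(default_factory=dict, repr=False)

    def iter_matrices(self) -> Iterator[pd.DataFrame]:
        """Regenerate the null matrices, one per iteration."""
        randomize = _RANDOMIZERS[self.method]
        pool = build_regional_pool(self.matrix)
        for it in range(self.iterations):
            yield randomize(self.matrix, pool, rng_seed=spawn_seed(self.rng_seed, "iter", it))

    def null_bray_curtis(self, subset: frozenset | set | None = None) -> np.ndarray:
        """Null pairwise Bray-Curtis values, shape (iterations, n_pairs).

        ``subset`` restricts both observed-column order and every null
        matrix to those taxa before computing distances. Pairs whose subset
        total is zero in some null matrix come back as NaN and are handled
        downstream. Results are cached per subset.
        """
        key = None if subset is None else frozenset(subset)
        if key in self._null_bc:
            return self._null_bc[key]
        cols = (
            slice(None)
            if key is None
            else self.matrix.columns.isin(key)
        )
        rows = []
        for null in self.iter_matrices():
            values = null.to_numpy() if key is None else null.to_numpy()[:, cols]
            rows.append(_pairwise_bc_condensed(values))
        result = np.vstack(rows)
        self._null_bc[key] = result
        return result

    def precompute(self, subsets: dict[str, frozenset | None]) -> dict[str, np.ndarray]:
        """Compute null dissimilarities for several subsets in one pass."""
        pending = {
            name: (None if s is None else frozenset(s))
            for name, s in subsets.items()
        }
        masks = {
            name: (slice(None) if key is None else self.matrix.columns.isin(key))
            for name, key in pending.items()
        }
        rows: dict[str, list[np.ndarray]] = {name: [] for name in pending}
        for null in self.iter_matrices():
            values = null.to_numpy()
            for name, mask in masks.items():
                sub = values if isinstance(mask, slice) else values[:, mask]
                rows[name].append(_pairwise_bc_condensed(sub))
        out = {}
        for name, key in pending.items():
            arr = np.vstack(rows[name])
            self._null_bc[key] = arr
            out[name] = arr
        return out


def generate_ensemble(
    matrix: pd.DataFrame,
    method: NullMethod,
    iterations: int = 1000,
    rng_seed: int = 0,
) -> NullEnsemble:
    """Build a null ensemble for an observed count matrix.

    The ensemble is lazy: matrices stream from the seed when needed, and two
    ensembles built with the same arguments are identical draw for draw.
    """
    if method not in _RANDOMIZERS:
        raise InvalidParameterError(f"method must be one of {sorted(_RANDOMIZERS)}")
    if iterations < 1:
        raise InvalidParameterError("iterations must be >= 1")
    validate_count_matrix(matrix, require_positive_rows=False)
    return NullEnsemble(matrix=matrix, method=method, iterations=iterations, rng_seed=rng_seed)
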