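"""Random subsampling of individuals: mock communities at fixed depths.

Sequencing a community of ~10^8 organisms captures only a tiny random
subset of them. That whole chain of random losses is modelled here as a
single draw WITHOUT replacement (multivariate hypergeometric) of ``depth``
individuals from the full community — the mock community standing in for a
sequencing profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .community import Community, InvalidInputError, InvalidParameterError

__all__ = ["DEFAULT_DEPTHS", "subsample", "subsample_matrix", "capture_stats"]

#: Depths (sequences per sample) spanning typical amplicon-survey effort.
DEFAULT_DEPTHS: tuple[int, ...] = (5_000, 10_000, 30_000, 50_000, 70_000, 100_000, 200_000)


def subsample(community: Community, depth: int, rng_seed: int = 0) -> Community:
    """Draw ``depth`` individuals without replacement from a community.

    Returns a community over the same taxon ids (zero-count taxa retained,
    so seed and mock share one taxon universe) whose total is exactly
    ``depth``.
    """
    total = community.total
    if not 0 < depth <= total:
        raise InvalidParameterError(
            f"depth must be in [1, {total}] (community total), got {depth}"
        )
    if depth == total:
        return Community(community.taxon_ids, community.abundances.copy())
    rng = substream(rng_seed, "subsample")
    # "marginals" scales with the number of taxa, not the 10^8 individuals
    counts = rng.multivariate_hypergeometric(
        community.abundances, depth, method="marginals"
    )
    return Community(community.taxon_ids, counts)


def subsample_matrix(matrix: pd.DataFrame, depth: int, rng_seed: int = 0) -> pd.DataFrame:
    """Row-wise :func:`subsample` with independent substreams per sample."""
    rows = []
    for i, (sample_id, row) in enumerate(matrix.iterrows()):
        com = Community(tuple(str(c) for c in matrix.columns), row.to_numpy())
        try:
            sub = subsample(com, depth, rng_seed=int(substream(rng_seed, "row", i).integers(0, 2**31)))
        except InvalidParameterError as err:
            raise InvalidParameterError(f"sample {sample_id!r}: {err}") from err
        rows.append(sub.abundances)
    return pd.DataFrame(np.vstack(rows), index=matrix.index, columns=matrix.columns)


def capture_stats(seed: Community, mock: Community) -> tuple[int, int]:
    """How much of the seed community the mock profile captured.

    Returns ``(observed_taxa, lost_taxa)``: taxa seen in the mock, and taxa
    present in the seed but missed entirely by the subsample. The two sum to
    the seed's richness.
    """
    if seed.taxon_ids != mock.taxon_ids:
        raise InvalidInputError("seed and mock must share the same taxon universe")
    observed = int(np.count_nonzero(mock.abundances))
    lost = int(np.count_nonzero((seed.abundances > 0) & (mock.abundances == 0)))
    return observed, lost
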