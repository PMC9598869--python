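"""Lognormal species-abundance-distribution (SAD) community simulator.

Builds full-scale "seed" communities — the ground truth a sequencing run
would sample from — and derives metacommunities from them by ecological
perturbations:

* *renaming* a fraction of taxa as new taxa (drift producing taxa not seen
  in other samples), and
* *shuffling* abundances among a fraction of taxa (dispersal limitation
  decoupling a taxon's local abundance from its identity).

Defaults target the soil-like scale of 10^4 taxa and 10^8 organisms per
community, whose fitted lognormal parameters come out at meanlog ~ 6.8 and
sdlog ~ 2.2 on natural logs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import spawn_seed, substream
from .community import (
    Community,
    InsufficientDataError,
    InvalidParameterError,
    matrix_from_communities,
)

__all__ = [
    "PerturbationSpec",
    "LognormalFit",
    "generate_pseudo_seed",
    "perturb",
    "build_seed_metacommunity",
    "fit_lognormal",
    "default_perturbation_design",
    "shadow_rename_map",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Fractions of taxa to relabel as new taxa and to abundance-shuffle."""

    rename_fraction: float = 0.0
    shuffle_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rename_fraction", "shuffle_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class LognormalFit:
    """Maximum-likelihood lognormal parameters of positive abundances.

    ``meanlog`` and ``sdlog`` are the mean and population standard deviation
    of natural-log abundances (dimensionless on the log scale).
    """

    meanlog: float
    sdlog: float


def generate_pseudo_seed(
    n_taxa: int,
    n_individuals: int,
    sdlog: float = 2.2,
    rng_seed: int = 0,
    taxon_prefix: str = "t",
) -> Community:
    """Draw a community of ``n_taxa`` taxa and exactly ``n_individuals``.

    Per-taxon relative abundances are a lognormal draw with the given
    ``sdlog``; the location parameter is irrelevant after normalisation and
    is implicitly ``ln(n_individuals / n_taxa) - sdlog**2 / 2`` on the count
    scale, so the expected abundance per taxon is ``n_individuals / n_taxa``.
    Individuals are allocated by a single multinomial draw over the
    normalised weights. Any taxon left with zero individuals is repaired to
    one by moving an individual from the currently most abundant taxon, so
    every declared taxon is present and the total is exact.
    """
    if n_taxa < 2:
        raise InvalidParameterError("n_taxa must be >= 2")
    if sdlog < 0:
        raise InvalidParameterError("sdlog must be >= 0")
    if n_individuals < n_taxa:
        raise InvalidParameterError(
            "n_individuals must be >= n_taxa so every taxon can hold >= 1 individual"
        )
    rng = substream(rng_seed, "pseudo-seed")
    log_weights = rng.normal(0.0, sdlog, size=n_taxa)
    # subtract the max before exponentiating: immune to overflow at large sdlog
    w = np.exp(log_weights - log_weights.max())
    w /= w.sum()
    counts = rng.multinomial(n_individuals, w)
    counts = _repair_zeros(counts)
    width = len(str(n_taxa))
    ids = tuple(f"{taxon_prefix}{i:0{width}d}" for i in range(1, n_taxa + 1))
    return Community(ids, counts)


def _repair_zeros(counts: np.ndarray) -> np.ndarray:
    counts = counts.copy()
    zeros = np.flatnonzero(counts == 0)
    for z in zeros:
        donor = int(np.argmax(counts))
        counts[donor] -= 1
        counts[z] += 1
    return counts


def shadow_rename_map(taxon_ids: Sequence[str], suffix: str = "*") -> dict[str, str]:
    """Stable rename map sending each taxon to its 'novel' counterpart id.

    Used when several samples of one metacommunity rename taxa: a taxon
    renamed in two samples maps to the *same* new id in both, so the novel
    taxon pool of the metacommunity is bounded by the original richness.
    """
    return {t: f"{t}{suffix}" for t in taxon_ids}


def perturb(
    base: Community,
    spec: PerturbationSpec,
    rng_seed: int = 0,
    rename_map: Mapping[str, str] | None = None,
) -> Community:
    """Apply drift/dispersal-mimicking perturbations to a community.

    A uniformly random subset of ``round(rename_fraction * n_taxa)`` taxa is
    relabelled as new taxa; an independently drawn subset of
    ``round(shuffle_fraction * n_taxa)`` taxa has its abundances permuted
    uniformly among that subset. The abundance multiset and the total number
    of individuals are conserved exactly.

    ``rename_map`` fixes the new identifier for each taxon; when omitted,
    fresh identifiers unique to this call are generated deterministically
    from ``rng_seed``.
    """
    n = len(base.taxon_ids)
    rng = substream(rng_seed, "perturb")
    n_rename = int(round(spec.rename_fraction * n))
    n_shuffle = int(round(spec.shuffle_fraction * n))

    abundances = base.abundances.copy()
    if n_shuffle > 1:
        shuffle_idx = rng.choice(n, size=n_shuffle, replace=False)
        abundances[shuffle_idx] = abundances[shuffle_idx][rng.permutation(n_shuffle)]
    elif n_shuffle == 1:
        rng.choice(n, size=1, replace=False)  # keep stream alignment

    ids = list(base.taxon_ids)
    if n_rename > 0:
        rename_idx = rng.choice(n, size=n_rename, replace=False)
        if rename_map is None:
            token = int(rng.integers(0, 2**63))
            rename_map = {
                ids[i]: f"{ids[i]}.n{token:016x}.{k}"
                for k, i in enumerate(rename_idx)
            }
        for i in rename_idx:
            ids[i] = rename_map[ids[i]]
    return Community(tuple(ids), abundances)


def default_perturbation_design(
    n_samples: int = 15, max_fraction: float = 0.5
) -> list[PerturbationSpec]:
    """Evenly graded perturbation levels for a metacommunity.

    Sample ``k`` (k = 0 .. n_samples-1) renames and shuffles each a fraction
    ``max_fraction * k / (n_samples - 1)`` of taxa, so the total perturbed
    portion spans 0 to ``2 * max_fraction`` (0 to 100% at the default) and
    the samples realise a wide gradient of pairwise dissimilarity.
    """
    if n_samples < 2:
        raise InvalidParameterError("n_samples must be >= 2")
    levels = [max_fraction * k / (n_samples - 1) for k in range(n_samples)]
    return [PerturbationSpec(v, v) for v in levels]


def build_seed_metacommunity(
    pseudo_seeds: Sequence[Community],
    specs: Sequence[PerturbationSpec],
    rng_seed: int = 0,
    shared_rename_map: bool = True,
) -> pd.DataFrame:
    """Perturb each pseudo seed by its spec and merge into one count matrix.

    Returns a sample x taxon matrix over the union of all taxon ids with
    absent taxa as 0. With ``shared_rename_map`` (the default) all samples
    rename through one stable taxon -> novel-taxon map, bounding the novel
    pool and giving a union of about twice the per-sample richness under the
    default design.
    """
    if len(pseudo_seeds) != len(specs):
        raise InvalidParameterError(
            f"got {len(pseudo_seeds)} pseudo seeds but {len(specs)} perturbation specs"
        )
    rmap = None
    if shared_rename_map:
        union: dict[str, None] = {}
        for seed_com in pseudo_seeds:
            for t in seed_com.taxon_ids:
                union.setdefault(t, None)
        rmap = shadow_rename_map(list(union))
    samples = {
        f"S{i:02d}": perturb(
            seed_com, spec, rng_seed=spawn_seed(rng_seed, "meta", i), rename_map=rmap
        )
        for i, (seed_com, spec) in enumerate(zip(pseudo_seeds, specs))
    }
    return matrix_from_communities(samples)


def fit_lognormal(community: Community | np.ndarray | Sequence[float]) -> LognormalFit:
    """MLE lognormal fit to the positive abundances of a community.

    Zeros are excluded (undefined on the log scale); ``meanlog`` is the mean
    and ``sdlog`` the population (1/n) standard deviation of the natural
    logs, which are the maximum-likelihood estimators for lognormal data.
    """
    ab = community.abundances if isinstance(community, Community) else np.asarray(community)
    positive = ab[ab > 0]
    if positive.size < 2:
        raise InsufficientDataError(
            "need at least 2 positive abundances to fit a lognormal"
        )
    logs = np.log(positive.astype(np.float64))
    return LognormalFit(meanlog=float(logs.mean()), sdlog=float(logs.std(ddof=0)))
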