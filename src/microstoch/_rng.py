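"""Deterministic RNG substream derivation.

Every stochastic operation in the package takes an integer seed and, where
it needs several independent streams (one per sample, per iteration, ...),
derives them through :func:`substream`. Streams are keyed by a master seed
plus a tuple of string/integer tags, so a fixed master seed reproduces the
whole experiment bit for bit while stages stay statistically independent.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def _tag_to_u32(tag: str | int) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) % (2**32)
    return zlib.crc32(str(tag).encode("utf-8"))


def substream(master_seed: int, *tags: str | int) -> np.random.Generator:
    """Return a Generator for the stream identified by ``(master_seed, *tags)``.

    The same arguments always yield an identical stream; differing tags give
    streams that are independent for all practical purposes (distinct
    ``SeedSequence`` spawn keys).
    """
    ss = np.random.SeedSequence(
        int(master_seed) % (2**32), spawn_key=tuple(_tag_to_u32(t) for t in tags)
    )
    return np.random.default_rng(ss)


def spawn_seed(master_seed: int, *tags: str | int) -> int:
    """A plain integer seed (< 2**31) derived from a tagged substream."""
    return int(substream(master_seed, *tags).integers(0, 2**31))
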