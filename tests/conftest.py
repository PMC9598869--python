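"""Shared fixtures: small hand-built tables and scaled-down simulations."""

import numpy as np
import pandas as pd
import pytest

from microstoch import (
    build_seed_metacommunity,
    default_perturbation_design,
    generate_pseudo_seed,
    subsample_matrix,
)


@pytest.fixture
def toy_matrix() -> pd.DataFrame:
    """4 samples x 5 taxa with unequal totals and one rare-ish taxon."""
    return pd.DataFrame(
        [
            [30, 10, 5, 0, 1],
            [25, 15, 0, 4, 2],
            [40, 5, 3, 2, 0],
            [20, 20, 4, 1, 1],
        ],
        index=["A", "B", "C", "D"],
        columns=["t1", "t2", "t3", "t4", "t5"],
    )


@pytest.fixture(scope="session")
def small_base():
    """A scaled pseudo seed: 300 taxa, 3x10^5 individuals."""
    return generate_pseudo_seed(300, 300_000, sdlog=2.2, rng_seed=42)


@pytest.fixture(scope="session")
def small_metacommunity(small_base):
    """10-sample metacommunity from the scaled base, graded perturbations."""
    return build_seed_metacommunity(
        [small_base] * 10, default_perturbation_design(10), rng_seed=7
    )


@pytest.fixture(scope="session")
def small_mock(small_metacommunity):
    """The scaled metacommunity rarefied to depth 2,000, empty columns kept."""
    return subsample_matrix(small_metacommunity, 2_000, rng_seed=11)
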