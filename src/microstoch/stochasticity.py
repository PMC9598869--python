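"""Stochasticity inference: the stochastic ratio and the Raup-Crick metric.

Both statistics compare observed pairwise Bray-Curtis structure with a null
ensemble. Writing C_ij for the observed similarity (1 - Bray-Curtis) of a
sample pair and E̅_ij for its mean null similarity:

* the **stochastic ratio** is ``E̅/C`` when E̅ < C (determinism made the pair
  more similar than the null) and ``(1-E̅)/(1-C)`` when E̅ >= C (determinism
  made it more dissimilar); both branches are smaller-over-larger, so
  ST ∈ [0, 1] and 1 means indistinguishable from the null;
* **RC_bray** is the rank of the observed dissimilarity within its null
  distribution, rescaled to [-1, 1] with ties split half-and-half. |RC| <=
  0.95 is read as stochastic assembly; RC > 0.95 (resp. < -0.95) as
  deterministic processes driving divergence (resp. convergence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import InvalidInputError
from .diversity import pairwise_beta
from .null_models import NullEnsemble

__all__ = [
    "stochastic_ratio_pair",
    "stochastic_ratio",
    "rc_bray_pair",
    "rc_bray",
    "classify_rc",
    "pair_stats",
    "RCClassification",
    "StochasticityResult",
]

#: Absolute tolerance for detecting observed == null ties in RC_bray.
RC_TIE_TOL = 1e-12


def stochastic_ratio_pair(C: float, E_bar: float) -> float:
    """Stochastic ratio of one sample pair from its observed and null similarity.

    Degenerate cases are the limits of the two branches: C = E̅ = 1 (pair and
    nulls all identical) gives 1; C = 1 with E̅ < 1 gives E̅.
    """
    if not (0.0 <= C <= 1.0 and 0.0 <= E_bar <= 1.0):
        raise InvalidInputError(f"similarities must be in [0, 1]: C={C}, E_bar={E_bar}")
    if E_bar < C:
        return E_bar / C  # C > 0 is implied by E_bar >= 0
    if C == 1.0:  # then E_bar == 1 as well
        return 1.0
    return (1.0 - E_bar) / (1.0 - C)


@dataclass(frozen=True)
class StochasticityResult:
    """Per-pair stochasticity table and its summary means.

    ``pairs`` columns: C (observed similarity), E_bar (mean null
    similarity), ST (stochastic ratio), RC (Raup-Crick), indexed by sample
    pair.
    """

    pairs: pd.DataFrame
    mean_st: float
    rc: "RCClassification"


def _aligned_null_bc(
    matrix: pd.DataFrame, ensemble: NullEnsemble, subset: frozenset | set | None
) -> tuple[pd.Series, np.ndarray]:
    if ensemble.matrix is not matrix and not ensemble.matrix.equals(matrix):
        raise InvalidInputError("ensemble was not generated from this matrix")
    observed = pairwise_beta(matrix, subset=None if subset is None else set(subset))
    null_bc = ensemble.null_bray_curtis(subset)
    if len(observed.excluded):
        # drop the same pairs from the null arrays to stay aligned
        n = matrix.shape[0]
        all_pairs = [
            (matrix.index[i], matrix.index[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        keep = [k for k, p in enumerate(all_pairs) if p not in set(observed.excluded)]
        null_bc = null_bc[:, keep]
    return observed.pairs, null_bc


def stochastic_ratio(
    matrix: pd.DataFrame,
    ensemble: NullEnsemble,
    subset: frozenset | set | None = None,
) -> tuple[pd.Series, float]:
    """Per-pair stochastic ratios and their unweighted mean.

    E̅_ij is the arithmetic mean of (1 - null Bray-Curtis) over the
    ensemble's iterations; the subset restriction (abundant or rare taxa)
    applies identically to the observed matrix and every null matrix.
    Null-matrix pairs with an undefined dissimilarity (empty subset rows)
    are skipped in the average for that pair.
    """
    obs_bc, null_bc = _aligned_null_bc(matrix, ensemble, subset)
    e_bar = 1.0 - np.nanmean(null_bc, axis=0)
    st = pd.Series(
        [
            stochastic_ratio_pair(1.0 - d, e)
            for d, e in zip(obs_bc.to_numpy(), e_bar)
        ],
        index=obs_bc.index,
        name="ST",
    )
    return st, float(st.mean())


def rc_bray_pair(observed_bc: float, null_bcs: np.ndarray) -> float:
    """Raup-Crick value of one pair from its null dissimilarity distribution.

    ``RC = 2 * ((#(null < obs) + 0.5 * #(null == obs)) / n - 0.5)``; ties are
    detected with an absolute tolerance of 1e-12 to absorb float noise.
    """
    nulls = np.asarray(null_bcs, dtype=np.float64)
    nulls = nulls[~np.isnan(nulls)]
    if nulls.size == 0:
        raise InvalidInputError("empty null dissimilarity distribution")
    ties = np.abs(nulls - observed_bc) <= RC_TIE_TOL
    below = (nulls < observed_bc) & ~ties
    frac = (below.sum() + 0.5 * ties.sum()) / nulls.size
    return float(2.0 * (frac - 0.5))


def rc_bray(
    matrix: pd.DataFrame,
    ensemble: NullEnsemble,
    subset: frozenset | set | None = None,
) -> pd.Series:
    """Per-pair RC_bray values against the ensemble's null distributions."""
    obs_bc, null_bc = _aligned_null_bc(matrix, ensemble, subset)
    values = [
        rc_bray_pair(d, null_bc[:, k]) for k, d in enumerate(obs_bc.to_numpy())
    ]
    return pd.Series(values, index=obs_bc.index, name="RC")


@dataclass(frozen=True)
class RCClassification:
    """Fractions of sample pairs in each Raup-Crick regime (they sum to 1)."""

    frac_above: float  # RC > 0.95: deterministic, divergent
    frac_below: float  # RC < -0.95: deterministic, convergent
    frac_stochastic: float  # |RC| <= 0.95


def classify_rc(rc_values) -> RCClassification:
    """Classify RC values with the +-0.95 cutoffs (boundary counts as stochastic)."""
    values = np.asarray(rc_values, dtype=np.float64)
    if values.size == 0:
        raise InvalidInputError("cannot classify an empty set of RC values")
    if np.any(np.abs(values) > 1.0 + 1e-12):
        raise InvalidInputError("RC values must lie in [-1, 1]")
    above = float(np.mean(values > 0.95))
    below = float(np.mean(values < -0.95))
    return RCClassification(above, below, 1.0 - above - below)


def pair_stats(
    matrix: pd.DataFrame,
    ensemble: NullEnsemble,
    subset: frozenset | set | None = None,
) -> StochasticityResult:
    """Joint per-pair table of C, E̅, ST and RC from one null ensemble."""
    obs_bc, null_bc = _aligned_null_bc(matrix, ensemble, subset)
    e_bar = 1.0 - np.nanmean(null_bc, axis=0)
    c = 1.0 - obs_bc.to_numpy()
    st = np.array([stochastic_ratio_pair(ci, ei) for ci, ei in zip(c, e_bar)])
    rc = np.array(
        [rc_bray_pair(d, null_bc[:, k]) for k, d in enumerate(obs_bc.to_numpy())]
    )
    pairs = pd.DataFrame(
        {"C": c, "E_bar": e_bar, "ST": st, "RC": rc}, index=obs_bc.index
    )
    return StochasticityResult(
        pairs=pairs, mean_st=float(st.mean()), rc=classify_rc(rc)
    )
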