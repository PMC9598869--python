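"""End-to-end experiment orchestration.

One experiment: simulate a full-scale seed metacommunity, rarefy it to a
series of sequencing depths, and at every depth (plus the full-scale
reference) compute observed beta-diversity, null beta-diversity under both
randomization methods, mean stochastic ratios and Raup-Crick fractions for
the whole community and its abundant/rare subcommunities. The outputs are
tidy tables; the difference between mock rows and the seed reference row
quantifies the bias that random sampling alone introduces.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from ._rng import spawn_seed
from .community import InvalidInputError, InvalidParameterError
from .diversity import partition_abundant_rare, pairwise_beta
from .null_models import generate_ensemble
from .rarefaction import DEFAULT_DEPTHS, subsample_matrix
from .sad import (
    build_seed_metacommunity,
    default_perturbation_design,
    generate_pseudo_seed,
)
from .stochasticity import pair_stats
from .io import write_count_table

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment", "compare_seed_vs_mock"]

logger = logging.getLogger(__name__)

#: Label used in the ``depth`` column for the full-scale (seed) reference rows.
SEED_DEPTH = 0


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one experiment; round-trips losslessly through YAML.

    The defaults are the study conditions: 15 communities of 10^4 taxa and
    10^8 organisms drawn from a lognormal SAD with sdlog 2.2, perturbation
    levels spanning 0-100% of taxa, seven rarefaction depths from 5,000 to
    200,000, both null methods at 1,000 iterations, and an 80% cumulative
    abundance cutoff between abundant and rare taxa.
    """

    n_taxa: int = 10_000
    n_individuals: int = 100_000_000
    sdlog: float = 2.2
    n_samples: int = 15
    max_perturbation_fraction: float = 0.5
    depths: tuple[int, ...] = DEFAULT_DEPTHS
    null_methods: tuple[str, ...] = ("shuffle", "proportional")
    iterations: int = 1000
    abundant_threshold: float = 0.80
    master_seed: int = 0

    def __post_init__(self) -> None:
        if list(self.depths) != sorted(set(self.depths)):
            raise InvalidParameterError("depths must be strictly increasing")
        if any(d <= 0 for d in self.depths):
            raise InvalidParameterError("depths must be positive")
        if max(self.depths) > self.n_individuals:
            raise InvalidParameterError("depths cannot exceed the community size")

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["depths"] = list(self.depths)
        data["null_methods"] = list(self.null_methods)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise InvalidParameterError(f"{path}: config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"{path}: unknown config keys {sorted(unknown)}")
        for key in ("depths", "null_methods"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class ExperimentResult:
    """Tidy result tables of one experiment run.

    Every table carries a ``depth`` column where 0 labels the full-scale
    seed reference; mock rows carry the actual sequencing depth.
    """

    config: ExperimentConfig
    richness: pd.DataFrame  # depth, sample_id, observed_taxa, lost_taxa
    beta: pd.DataFrame  # depth, subset, mean_bray_curtis, n_pairs
    summary: pd.DataFrame  # depth, subset, method, null_beta, mean_ST, frac_*
    pair_tables: dict = field(default_factory=dict, repr=False)
    seed_matrix: pd.DataFrame | None = field(default=None, repr=False)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.richness.to_csv(outdir / "richness_by_depth.csv", index=False)
        self.beta.to_csv(outdir / "observed_beta.csv", index=False)
        self.summary.to_csv(outdir / "stochasticity_summary.csv", index=False)
        pairs = []
        for (depth, subset, method), table in self.pair_tables.items():
            t = table.reset_index()
            t.insert(0, "depth", depth)
            t.insert(1, "subset", subset)
            t.insert(2, "method", method)
            pairs.append(t)
        if pairs:
            pd.concat(pairs, ignore_index=True).to_csv(
                outdir / "pair_stats.csv", index=False
            )
        if self.seed_matrix is not None:
            write_count_table(self.seed_matrix, outdir / "seed_metacommunity.tsv")


def _analyse_matrix(matrix, depth, config, seed_tag):
    """Beta, null beta, ST and RC for one matrix at one depth, all subsets.

    The abundant and rare subcommunities are analysed as count tables in
    their own right: the partition of this matrix defines a submatrix per
    subset (empty columns dropped), and the null ensembles are generated
    from that submatrix with its own regional pool — mirroring how
    subcommunity null-model analyses are run on real data.
    """
    partition = partition_abundant_rare(matrix, config.abundant_threshold)
    submatrices = {"whole": matrix}
    for name, taxa in (("abundant", partition.abundant_taxa), ("rare", partition.rare_taxa)):
        sub = matrix.loc[:, matrix.columns.isin(taxa)]
        submatrices[name] = sub.loc[:, sub.sum(axis=0) > 0]
    beta_rows, summary_rows, pair_tables = [], [], {}
    for name, sub in submatrices.items():
        observed = pairwise_beta(sub)
        beta_rows.append(
            {
                "depth": depth,
                "subset": name,
                "mean_bray_curtis": observed.mean,
                "n_pairs": len(observed.pairs),
            }
        )
    for method in config.null_methods:
        t0 = time.perf_counter()
        for name, sub in submatrices.items():
            ensemble = generate_ensemble(
                sub,
                method,
                iterations=config.iterations,
                rng_seed=spawn_seed(config.master_seed, "nulls", seed_tag, method, name),
            )
            stats = pair_stats(sub, ensemble)
            null_beta = float(1.0 - stats.pairs["E_bar"].mean())
            summary_rows.append(
                {
                    "depth": depth,
                    "subset": name,
                    "method": method,
                    "null_beta": null_beta,
                    "mean_ST": stats.mean_st,
                    "frac_above": stats.rc.frac_above,
                    "frac_below": stats.rc.frac_below,
                    "frac_stochastic": stats.rc.frac_stochastic,
                }
            )
            pair_tables[(depth, name, method)] = stats.pairs
        logger.info(
            "depth=%s method=%s: %d iterations in %.1fs",
            depth, method, config.iterations, time.perf_counter() - t0,
        )
    return beta_rows, summary_rows, pair_tables


def run_experiment(config: ExperimentConfig, keep_matrices: bool = True) -> ExperimentResult:
    """Run the full simulation experiment described by ``config``.

    Stages: generate one full-scale pseudo seed community; derive the
    15-sample seed metacommunity by graded rename/shuffle perturbations;
    analyse it as the reference; then for each depth subsample every sample
    to that depth and repeat the analysis (partition, observed beta, null
    ensembles under each method, ST, RC). Fully reproducible from
    ``config.master_seed``.
    """
    t0 = time.perf_counter()
    base = generate_pseudo_seed(
        config.n_taxa,
        config.n_individuals,
        sdlog=config.sdlog,
        rng_seed=spawn_seed(config.master_seed, "base"),
    )
    design = default_perturbation_design(
        config.n_samples, config.max_perturbation_fraction
    )
    seed_matrix = build_seed_metacommunity(
        [base] * config.n_samples,
        design,
        rng_seed=spawn_seed(config.master_seed, "metacommunity"),
    )
    logger.info(
        "seed metacommunity: %d samples x %d taxa (%.1fs)",
        *seed_matrix.shape, time.perf_counter() - t0,
    )
    seed_richness = (seed_matrix > 0).sum(axis=1)

    richness_rows = [
        {"depth": SEED_DEPTH, "sample_id": s, "observed_taxa": int(r), "lost_taxa": 0}
        for s, r in seed_richness.items()
    ]
    beta_rows, summary_rows, pair_tables = _analyse_matrix(
        seed_matrix, SEED_DEPTH, config, "seed"
    )

    for depth in config.depths:
        mock = subsample_matrix(
            seed_matrix, depth, rng_seed=spawn_seed(config.master_seed, "depth", depth)
        )
        observed = (mock > 0).sum(axis=1)
        for s in mock.index:
            richness_rows.append(
                {
                    "depth": depth,
                    "sample_id": s,
                    "observed_taxa": int(observed[s]),
                    "lost_taxa": int(seed_richness[s] - observed[s]),
                }
            )
        # drop empty columns: cheaper distance computations, same values
        mock = mock.loc[:, mock.sum(axis=0) > 0]
        b, s, p = _analyse_matrix(mock, depth, config, f"depth-{depth}")
        beta_rows += b
        summary_rows += s
        pair_tables.update(p)

    logger.info("experiment complete in %.1fs", time.perf_counter() - t0)
    return ExperimentResult(
        config=config,
        richness=pd.DataFrame(richness_rows),
        beta=pd.DataFrame(beta_rows),
        summary=pd.DataFrame(summary_rows),
        pair_tables=pair_tables,
        seed_matrix=seed_matrix if keep_matrices else None,
    )


def run_replicates(config: ExperimentConfig, n_replicates: int) -> list[ExperimentResult]:
    """Independent replicate runs with seeds derived from the master seed."""
    return [
        run_experiment(
            replace(config, master_seed=spawn_seed(config.master_seed, "replicate", r)),
            keep_matrices=False,
        )
        for r in range(n_replicates)
    ]


def compare_seed_vs_mock(result: ExperimentResult) -> pd.DataFrame:
    """Bias table: mock minus seed, per (depth, subset, method).

    ``delta_beta`` is the observed beta-diversity overestimation caused by
    subsampling alone; ``delta_st`` the stochastic-ratio overestimation.
    """
    seed_beta = result.beta[result.beta["depth"] == SEED_DEPTH]
    mock_beta = result.beta[result.beta["depth"] != SEED_DEPTH]
    if seed_beta.empty or mock_beta.empty:
        raise InvalidInputError("result must contain both seed reference and mock rows")
    seed_b = seed_beta.set_index("subset")["mean_bray_curtis"]
    seed_sum = result.summary[result.summary["depth"] == SEED_DEPTH].set_index(
        ["subset", "method"]
    )
    rows = []
    for _, row in result.summary[result.summary["depth"] != SEED_DEPTH].iterrows():
        key = (row["subset"], row["method"])
        mock_b = result.beta.loc[
            (result.beta["depth"] == row["depth"])
            & (result.beta["subset"] == row["subset"]),
            "mean_bray_curtis",
        ].iloc[0]
        rows.append(
            {
                "depth": row["depth"],
                "subset": row["subset"],
                "method": row["method"],
                "delta_beta": float(mock_b - seed_b[row["subset"]]),
                "delta_st": float(row["mean_ST"] - seed_sum.loc[key, "mean_ST"]),
                "delta_frac_stochastic": float(
                    row["frac_stochastic"] - seed_sum.loc[key, "frac_stochastic"]
                ),
            }
        )
    return pd.DataFrame(rows).sort_values(["subset", "method", "depth"]).reset_index(drop=True)
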