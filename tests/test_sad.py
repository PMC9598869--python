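"""Simulator tests: SAD generation, perturbation, metacommunity assembly, fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microstoch import (
    Community,
    PerturbationSpec,
    bray_curtis,
    build_seed_metacommunity,
    default_perturbation_design,
    fit_lognormal,
    generate_pseudo_seed,
    perturb,
)
from microstoch.community import InsufficientDataError, InvalidParameterError


class TestGeneratePseudoSeed:
    def test_totals_and_richness_exact(self):
        com = generate_pseudo_seed(500, 100_000, sdlog=2.2, rng_seed=1)
        assert com.total == 100_000
        assert com.richness == 500
        assert len(com.taxon_ids) == 500

    def test_minimal_equal_weight_community(self):
        com = generate_pseudo_seed(5, 5, sdlog=0.0, rng_seed=7)
        assert list(com.abundances) == [1, 1, 1, 1, 1]

    def test_rejects_too_few_individuals(self):
        with pytest.raises(InvalidParameterError):
            generate_pseudo_seed(10, 9, sdlog=1.0, rng_seed=0)

    def test_reproducible(self):
        a = generate_pseudo_seed(100, 10_000, rng_seed=3)
        b = generate_pseudo_seed(100, 10_000, rng_seed=3)
        assert a.taxon_ids == b.taxon_ids
        assert np.array_equal(a.abundances, b.abundances)

    def test_lognormal_mean_identity(self):
        """ln(N/S) ~ meanlog + sdlog^2/2 (mean of a lognormal), within noise."""
        com = generate_pseudo_seed(10_000, 100_000_000, sdlog=2.2, rng_seed=5)
        fit = fit_lognormal(com)
        expected = math.log(100_000_000 / 10_000)
        assert fit.meanlog + fit.sdlog**2 / 2 == pytest.approx(expected, abs=0.25)


class TestFitLognormal:
    @pytest.mark.parametrize(
        "abundances, meanlog, sdlog",
        [
            (np.array([math.e, math.e, math.e]), 1.0, 0.0),
            (np.array([1.0, math.e**2]), 1.0, 1.0),
        ],
    )
    def test_hand_computed_fits(self, abundances, meanlog, sdlog):
        fit = fit_lognormal(abundances)
        assert fit.meanlog == pytest.approx(meanlog, abs=1e-12)
        assert fit.sdlog == pytest.approx(sdlog, abs=1e-12)

    def test_zeros_excluded(self):
        fit = fit_lognormal(np.array([0, 0, 1, math.e**2]))
        assert fit.meanlog == pytest.approx(1.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_lognormal(np.array([0, 0, 5]))

    def test_parameter_recovery_on_direct_samples(self):
        """MLE recovers (meanlog, sdlog) within 3 standard errors at n = 10^4."""
        rng = np.random.default_rng(123)
        n, mu, sigma = 10_000, 2.0, 1.5
        sample = np.exp(rng.normal(mu, sigma, size=n))
        fit = fit_lognormal(sample)
        se_mean = sigma / math.sqrt(n)
        se_sd = sigma / math.sqrt(2 * n)
        assert abs(fit.meanlog - mu) < 3 * se_mean
        assert abs(fit.sdlog - sigma) < 3 * se_sd


class TestPerturb:
    @pytest.fixture
    def base(self):
        return Community(("a", "b", "c", "d"), np.array([40, 30, 20, 10]))

    def test_identity_when_no_perturbation(self, base):
        out = perturb(base, PerturbationSpec(0, 0), rng_seed=1)
        assert out.taxon_ids == base.taxon_ids
        assert np.array_equal(out.abundances, base.abundances)
        assert bray_curtis(base.abundances, out.abundances) == 0.0

    def test_full_rename_gives_disjoint_support(self, base):
        out = perturb(base, PerturbationSpec(1.0, 0), rng_seed=2)
        assert not set(out.taxon_ids) & set(base.taxon_ids)
        assert sorted(out.abundances) == sorted(base.abundances)

    def test_abundance_multiset_conserved(self, base):
        for seed in range(5):
            out = perturb(base, PerturbationSpec(0.5, 0.75), rng_seed=seed)
            assert sorted(out.abundances) == sorted(base.abundances)
            assert out.total == base.total

    def test_full_shuffle_matches_exhaustive_enumeration(self):
        """BC(base, full shuffle) distribution equals brute force over all 3! permutations."""
        base = Community(("a", "b", "c"), np.array([3, 2, 1]))
        # oracle: enumerate all 6 permutations of the abundance vector
        import itertools

        expected = sorted(
            round(bray_curtis(base.abundances, np.array(p)), 12)
            for p in itertools.permutations([3, 2, 1])
        )
        observed = [
            round(
                bray_curtis(
                    base.abundances,
                    perturb(base, PerturbationSpec(0, 1.0), rng_seed=s)
                    .to_series()
                    .reindex(list(base.taxon_ids))
                    .to_numpy(),
                ),
                12,
            )
            for s in range(600)
        ]
        assert set(observed) <= set(expected)
        # every permutation appears; uniform => each with prob 1/6
        counts = {v: observed.count(v) for v in set(observed)}
        # BC values collapse over permutations; compare against enumerated frequencies
        from collections import Counter

        exp_freq = Counter(expected)
        for v, c in counts.items():
            assert c / 600 == pytest.approx(exp_freq[v] / 6, abs=0.08)

    def test_rename_monotonically_increases_dissimilarity(self, small_base):
        """E[Bray-Curtis(base, perturbed)] is non-decreasing in rename fraction."""
        levels = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for f in levels:
            values = [
                bray_curtis(
                    small_base.to_series().to_numpy(),
                    perturb(small_base, PerturbationSpec(f, 0.0), rng_seed=s)
                    .to_series()
                    .reindex(list(small_base.taxon_ids), fill_value=0)
                    .to_numpy(),
                )
                for s in range(20)
            ]
            means.append(np.mean(values))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))
        assert means[0] == 0.0 and means[-1] == 1.0

    @given(
        rename=st.floats(0, 1),
        shuffle=st.floats(0, 1),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_total_conserved_for_any_spec(self, rename, shuffle, seed):
        base = Community(("a", "b", "c", "d", "e"), np.array([9, 7, 5, 3, 1]))
        out = perturb(base, PerturbationSpec(rename, shuffle), rng_seed=seed)
        assert out.total == base.total
        assert sorted(out.abundances) == [1, 3, 5, 7, 9]


class TestBuildSeedMetacommunity:
    def test_unperturbed_rows_identical(self, small_base):
        mat = build_seed_metacommunity(
            [small_base] * 4, [PerturbationSpec(0, 0)] * 4, rng_seed=3
        )
        assert mat.shape == (4, 300)
        assert (mat.nunique(axis=0) == 1).all()

    def test_full_rename_doubles_taxon_pool(self, small_base):
        mat = build_seed_metacommunity(
            [small_base] * 2,
            [PerturbationSpec(0, 0), PerturbationSpec(1.0, 0)],
            rng_seed=3,
            shared_rename_map=False,
        )
        assert mat.shape[1] == 2 * 300

    def test_mismatched_lengths_rejected(self, small_base):
        with pytest.raises(InvalidParameterError):
            build_seed_metacommunity([small_base] * 3, [PerturbationSpec(0, 0)] * 2)

    def test_default_design_beta_consistent_with_independent_recount(
        self, small_metacommunity
    ):
        """Mean pairwise BC is positive, < 1, and equals a scipy recomputation."""
        from scipy.spatial.distance import pdist

        from microstoch import pairwise_beta

        result = pairwise_beta(small_metacommunity)
        oracle = pdist(small_metacommunity.to_numpy().astype(float), "braycurtis")
        assert 0 < result.mean < 1
        np.testing.assert_allclose(result.pairs.to_numpy(), oracle, atol=1e-12)

    def test_shared_rename_map_bounds_union(self, small_base):
        """With the shared novel-id map the union stays ~2x the base richness."""
        mat = build_seed_metacommunity(
            [small_base] * 10, default_perturbation_design(10), rng_seed=7
        )
        assert 300 < mat.shape[1] <= 600


def test_seed_scale_fit_recovers_printed_parameters():
    """Full-scale community fits meanlog ~ 6.8, sdlog ~ 2.2 on natural logs."""
    com = generate_pseudo_seed(10_000, 100_000_000, sdlog=2.2, rng_seed=9)
    fit = fit_lognormal(com)
    assert fit.meanlog == pytest.approx(6.80, abs=0.10)
    assert fit.sdlog == pytest.approx(2.20, abs=0.05)
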