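# Methods

## The simulation model

The package studies one question: when a community profile is a small
random sample of a much larger community, how do β-diversity and
null-model stochasticity metrics computed on the profile deviate from the
values of the full community? Everything is therefore built around a pair
of objects whose relationship is exactly known — a full-scale *seed*
metacommunity, and *mock* metacommunities obtained from it by subsampling
alone. Any difference between metrics on the two is, by construction, a
pure random-sampling effect: the simulator deliberately collapses the whole
profiling chain (extraction, PCR, sequencing, rarefaction) into a single
draw of organisms without replacement, so the bias it measures is a lower
bound on what real pipelines incur.

### Seed communities

A pseudo seed community has S taxa and exactly N individuals
(defaults S = 10⁴, N = 10⁸, the scale of a gram of soil). Per-taxon
weights are `exp(σZ)` with `Z ~ N(0, 1)` i.i.d. and σ = `sdlog` (default
2.2); individuals are allocated in one multinomial draw over the
normalised weights. Because the weights are normalised, the location
parameter of the generating lognormal is immaterial; the *fitted* location
comes out at `ln(N/S) − σ²/2 ≈ 6.79` by the lognormal mean identity, and
the package's maximum-likelihood fit (mean and population SD of
natural-log positive counts, zeros excluded) recovers meanlog ≈ 6.80 and
sdlog ≈ 2.20 at the default scale, matching values reported for
environmental microbiomes. Rarefied to 30,000 reads, the same fit
collapses to ≈ (1.0, 1.15) — the version of the community a sequencer
actually sees.

Two numerical details. Any taxon allocated zero individuals is raised to
one by moving an individual from the most abundant taxon (the community
declares exactly S taxa present; at N/S = 10⁴ expected individuals per
taxon such repairs are vanishingly rare). And a single community's fitted
meanlog carries a noise term of SD ≈ 0.11 from the normalisation by the
heavy-tailed weight sum (`sd(Σw)/E(Σw) = sqrt((e^{σ²}−1)/S)`), so
across-community means — not single draws — are the stable quantities.

### Perturbation design

The 15-sample metacommunity derives every sample from **one shared base
community**. Sample k (k = 0…14) renames a uniformly random fraction
`0.5·k/14` of taxa as new taxa (drift producing taxa unseen elsewhere) and
independently shuffles abundances among another fraction `0.5·k/14` of
taxa (dispersal limitation), so the *total* perturbed portion spans 0–100%
across samples. Renaming inside a metacommunity goes through one stable
taxon → novel-taxon map: a taxon renamed in two samples gets the same
novel identifier in both. This bounds the taxon union at about 2S
(≈ 2×10⁴ with the defaults) and is what makes graded, partially-shared
novelty possible; with per-sample fresh identifiers the union would grow
to ~8.5×10⁴ and most sample pairs would be nearly disjoint. Standalone
`perturb()` calls without a rename map do generate call-unique fresh ids.

This design was the main genuinely open choice (the exact published
design is not available). The alternatives — independent base communities
per sample, or rename = shuffle = k/14 each — produce metacommunities
where almost every pair is close to maximally dissimilar (with
independent lognormal draws the expected pairwise Bray–Curtis is already
`1 − 2Φ(−σ/√2) ≈ 0.88`), leaving no β-diversity gradient. The adopted
design realises pairwise Bray–Curtis from ≈ 0.10 to ≈ 0.82 (mean ≈ 0.61)
at full scale, the gradient regime the downstream analyses are about. The
trade-off is real and documented: the alternative k/14-each design raises
the full-scale rare-subcommunity stochastic ratio by ~0.1 while pushing
observed mock β-diversity above the regime studied here; no simple design
reproduces every published summary number simultaneously (see
"Limitations").

### Rarefaction

`subsample` draws `depth` individuals **without replacement**
(multivariate hypergeometric, "marginals" method, so cost scales with the
number of taxa rather than the 10⁸ individuals). At full depth the draw is
the identity — the invariant the tests lean on — and at seed scale it is
numerically indistinguishable from multinomial sampling. Zero-count taxa
are retained so seed and mock share one taxon universe; analysis entry
points drop all-zero columns where that is safe. Default depth series:
5,000, 10,000, 30,000, 50,000, 70,000, 100,000, 200,000 reads per sample.

## Null models and stochasticity metrics

The regional pool of a matrix is its set of taxa with positive pooled
count, each carrying an occurrence frequency (number of samples where
present) and a pooled relative abundance. Both randomization methods fix
each sample's richness exactly, choosing the occupied taxa by weighted
sampling without replacement with weights equal to occurrence frequency.
This is implemented by the exponential race (`key_i = Exp(1)/w_i`, keep
the k smallest), which has exactly the law of successive weighted draws;
the tests verify the occupancy distribution against exhaustive
enumeration. The **shuffle** method then permutes the sample's observed
abundance multiset onto the chosen taxa (totals, richness and the
multiset all conserved exactly); the **proportional** method gives each
occupied taxon a floor of one individual — without which a plain
multinomial would violate the fixed-richness constraint — and allocates
the remaining `total − richness` individuals by one multinomial draw with
probabilities proportional to the occupied taxa's regional relative
abundances. Ensembles (default 1,000 iterations; 100 in the fast profile
used by the test suite and the acceptance script) are lazy: a stored
(matrix, method, seed) triple regenerates matrices on demand, and only
pairwise null dissimilarities are cached, bounding memory at
iterations × n_pairs per analysed subset.

Per pair, the stochastic ratio is `E̅/C` when `E̅ < C` and
`(1−E̅)/(1−C)` otherwise, with C the observed Bray–Curtis similarity and
E̅ the mean null similarity. Degenerate cases are fixed by the branch
limits: C = E̅ = 1 gives 1; C = 1 with E̅ < 1 gives E̅ (and C = 0 with
E̅ = 0 gives 1 via the second branch). The summary is the unweighted mean
over pairs. RC uses the half-weight tie convention with an absolute tie
tolerance of 1e−12; classification cutoffs are strict (`RC > 0.95`,
`RC < −0.95`), the boundary counting as stochastic.

**Subcommunities.** The abundant set is the shortest prefix of taxa —
ranked by total count, ties broken by identifier — whose cumulative share
reaches the threshold (default 0.80); the partition is recomputed for
every matrix (each depth gets its own). Subcommunity β-diversity uses raw
counts restricted to the subset, without renormalisation. Subcommunity
stochasticity treats the subset as a count table in its own right: null
ensembles are generated *from the subcommunity matrix* with its own
regional pool, the way per-subcommunity null-model analyses are run on
real data. The alternative — restricting whole-community null matrices to
the subset — makes shuffle nulls scatter rare abundance onto abundant
columns and drives rare-subcommunity null profiles to near-total
dissimilarity; it is available through the `subset` argument of the
metric functions but is not what the pipeline reports.

## Reproducibility

One master seed drives everything. Each stochastic stage derives an
independent substream via `SeedSequence(master, spawn_key=hash(tags))`
keyed by stage name and sample/iteration index, so results are bitwise
reproducible, stages are statistically independent, and regenerating an
ensemble from its provenance is exact. Derived integer seeds stay below
2³¹.

## Problem sizes

Full-scale runs (15 × 10⁸ individuals, ~2×10⁴ taxa) are cheap because all
heavy steps are closed-form draws: a seed metacommunity builds in under a
second, and a 100-iteration null ensemble with all pairwise distances
takes a few seconds. The acceptance script runs the complete full-scale
computation in well under a minute. The test suite's qualitative-direction
checks use scaled replicates (300 taxa, 3×10⁵ individuals, 10 samples,
30-iteration ensembles, 10 replicates) — directions of the effects, not
magnitudes, are asserted there.

## What passing tests do and do not show

The simulator emulates random sampling only. It does not model
amplification or extraction bias, sequencing error, chimeras, copy-number
variation, compositionality corrections, or phylogenetic structure — so
agreement between the package's numbers and its reference values shows
the *sampling* component of stochasticity bias is reproduced, and nothing
about those other processes (which would plausibly make real-data biases
larger). Phylogeny-aware metrics (βNTI, UniFrac) are out of scope by
design.

## Limitations

* The perturbation design is a declared convention calibrated to the
  published β-diversity gradient of the seed communities, not a published
  protocol; magnitudes that depend on the detailed mixture of pairwise
  dissimilarities (most visibly the full-scale whole-community stochastic
  ratio under proportional nulls, where the package obtains ≈ 0.6) shift
  with that choice even while every qualitative direction — β inflation
  strongest for rare taxa, overestimated mock stochasticity, opposite
  biases of the two null methods — is robust across designs and
  replicates.
* Occupancy weighting implements "frequency-proportional" occupancy as
  successive weighted draws; other weighted-without-replacement laws
  (e.g. conditional Poisson) satisfy the same contract and could shift
  null β-diversity by small amounts.
* Bray–Curtis is the only dissimilarity; the stochastic ratio is the plain
  two-branch pairwise form (no normalized-NST or modified-ratio variants).
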