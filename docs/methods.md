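# Methods

## Model and assumptions

The simulator is an individual-based, zero-sum Moran process in a local
community of fixed size `J`, coupled to a fixed regional metacommunity.
One generation is defined as `J` death–birth events; snapshots and the
stopping rule operate on generation boundaries. Selection acts on the
death event only: at every event the death probabilities are the chosen
model's rates normalized to sum to one, the replacement parent is uniform
among the `J−1` survivors, and immigration (rate `m`) and point-mutation
speciation (probability `ν` per birth) are the only colonization channels.
Intraspecific trait variation is neglected: all conspecifics carry the
species trait, which is what allows the pairwise and β kernels to be
aggregated to species level exactly:

    q(a) = β_intra (n_a − 1) + β_inter Σ_{b≠a} n_b exp(−s_E (z_a − z_b)²)

This identity is the package's main computational device. The event loop
maintains the per-species kernel sums incrementally (O(S) per event) and
refreshes them in full (O(S²)) once per generation to bound floating-point
drift; the aggregated rates are tested against the naive O(J²) double loop
at 1e-10 on randomized communities. The `β_intra < β_inter` regime
(no density dependence) is rejected at parameter validation; exploratory
runs collapse to monodominance there and the regime is out of scope.

Equilibration is measured by Λ, the fraction of individuals descending
from lineages that colonized (immigration or in-situ speciation) after the
start. The community is initialized as `J` copies of a single founder
species drawn abundance-weighted from the metacommunity, so Λ measures the
erasure of the founding population. Runs stop at `Λ ≥ lambda_target` or at
a hard generation cap, in which case the trajectory is returned with a
`truncated` flag rather than an exception.

Degenerate death-rate vectors (possible under filtering when every
individual sits exactly at the optimum) fall back to the uniform vector
with a warning — the `s_E → 0`-consistent completion of the normalization.
Exponent arguments are clamped at −700 and kernel values below 1e-300
treated as zero to avoid denormal slowdowns.

Two open conventions were fixed as follows: the community mean trait used
by the mean-competition kernel is recomputed *before* each death event;
and a new species' trait is its parent's plus a Normal(0, σ_sp) step with
σ_sp defaulting to 10% of the metacommunity trait SD (logged in every
run's parameters).

## Metacommunity

The regional pool is static: log-series relative abundances (shape
parameter 0.98 by default) and one trait per species, generated either by
Brownian motion along a simulated Yule tree (default; phylogenetically
clumped traits) or as iid normal draws. The pool trait mean and SD used as
the reference for trait-divergence statistics are abundance-weighted,
because the local community samples individuals, not species. The
filtering optimum `z_E` defaults to the pool trait mean; both the optimum
and the trait model are configurable.

## Coalescent layer

Each extant species' genetic diversity comes from a haploid, single-locus,
no-recombination Hudson coalescent with infinite-sites mutation. The
species' recorded abundance trajectory (per-generation resolution by
default), scaled by `α`, defines piecewise-constant sizes `Ne(t)` backward
from the sampling point; each interval between recorded boundaries carries
the abundance at its older boundary, so a size change recorded at
generation `g` places the step exactly at `g`. Consecutive equal sizes are
merged. Lineages older than the species' colonization of the local
community enter a panmictic source pool (default haploid size 1e5) — the
simplest completion, since no regional genetic model is specified.
Defaults emulate a COI-like barcode: 570 bp, 10 haplotypes (never more
than the species' census abundance, with a floor of two), μ = 1e-7 per
site per generation. π is the mean pairwise difference per site;
correctness anchors are E[π] = θ = 2 Ne μ and E[TMRCA] = Ne for a pair at
constant size, a bottleneck-sensitivity check, the Ne·c / μ÷c scaling
identity, and agreement with msprime under a shared two-epoch demography.

## Summary statistics

One fixed-order, named vector per community (31 columns; see
`ecoassembly.sumstats.FEATURE_COLUMNS`): richness S; Λ when known; four
moments per axis — SAD moments on log abundances (the convention for
abundance data), trait and genetic moments species-weighted; Hill numbers
of orders 1–4 per axis; the three cross-axis Spearman correlations; and
abundance-weighted local-minus-regional trait mean and SD differences.
Genetic Hill numbers treat per-species π values normalized to proportions
as the diversity being partitioned. Trait Hill numbers are Chiu–Chao
attribute diversities with pairwise distances normalized by the
abundance-weighted mean distance Q, making them invariant to trait-axis
rescaling; they reduce to the abundance Hill number for equally abundant,
equally spaced species (the reduction is exact only in that case). Hill
orders and the moment conventions are config-switchable.

Undefined features (shape moments with fewer than 3–4 species, rank
correlations or trait diversities of degenerate communities, masked axes)
carry NaN sentinels, never silent zeros. The inference layer drops
sentinel-bearing *rows* at training time with a warning — imputation would
blur exactly the low-richness signal that distinguishes strong filtering —
and masked-out axes drop their *columns*.

## Inference

Random forest (1000 trees, library defaults otherwise, seed recorded),
features restricted to an axis mask: `sad+gen`, `trait+gen`, or `all`.
Richness is available under every mask (any axis implies a species list);
Λ is recorded in tables but never used as a feature, since it is not an
empirical observable. Class probabilities are the forest's averaged
per-tree class votes; the pairwise+β-collapsed view sums the two columns.
Accuracy is assessed by stratified 5-fold cross-validation pooled into a
single confusion matrix. The PCA view standardizes columns, drops
zero-variance columns with a warning, and tags scores by model and Λ bin.

## Problem sizes and priors

Two built-in batch configurations:

- `default_config` — wide priors for full-scale work: J uniform in
  [500, 2000], m log-uniform [1e-4, 1e-2], s_E log-uniform [0.001, 1],
  ν zero with probability 0.25 else log-uniform [1e-4, 5e-3],
  β_intra/β_inter log-uniform [1, 30] with β_inter = 1, α log-uniform
  [100, 5000], Λ target drawn from {0.25, 0.5, 0.75, 1}.
- `desk_config` — the package's reproduction scale, used by the test suite
  and `scripts/acceptance.py`: 500 simulations per model, J uniform in
  [500, 1000], m log-uniform [1e-3, 1e-2] (the narrower immigration range
  keeps equilibration times desk-sized), hard cap 2500 generations
  (truncated runs keep their realized Λ, which is itself a modelled
  covariate), other priors as above.

Every stage's seed derives deterministically from the master seed and the
(model, run index) pair, so batches are reproducible and resumable.

At the desk scale (seed 1) the classifier reaches 55% overall accuracy
with trait+genetic data, 42% with SAD+genetic, 56% with all three axes
(60% with pairwise and β-competition collapsed), against a 20% chance
floor — the qualitative ordering (trait data help most; all axes help
more; pairwise/β partially interchangeable) at roughly one-tenth the
training size of a full-scale run, where the gap between two- and
three-axis configurations is larger.

## What the generator does and does not emulate

Synthetic batches emulate: log-series regional abundance structure,
phylogenetically correlated (or iid) regional traits, demographic
stochasticity, partial equilibration (mixed Λ), and mtDNA-like
single-locus diversity tied to demographic history. They do not emulate:
intraspecific trait variation, multi-locus or recombining genetic data,
observation/sampling error on any axis, species-pair-specific interaction
matrices, or dynamic metacommunities. Passing tests therefore demonstrate
internal consistency of the method and recoverability of the generating
process *under the model's own assumptions*, not performance on field
data.

## Known limitations

- The confusion structure at desk scale differs from full scale: the
  largest misclassification cell is mean-competition → pairwise (with
  β → neutral second), rather than within the pairwise/β pair. Both
  confusions are mechanistically expected — mean competition is the
  mean-field limit of pairwise competition, and pairwise/β communities can
  resemble neutral ones ("emergent neutrality") — but the dominant cell is
  scale- and prior-dependent.
- The even-spacing (limiting-similarity) trait signature of pairwise
  competition is regime-dependent. With the default Brownian-tree pool
  (trait SD ≈ 1.5) and s_E = 0.1, the kernel width 1/√s_E ≈ 3.2 spans the
  occupied trait axis, so competition is nearly uniform across traits and
  the adjacent-gap CV of pairwise communities is *not* below neutral;
  the signature appears under stronger selection (s_E ≳ 1) or a narrower
  trait scale, where the kernel resolves trait differences. The
  bimodalization signature of mean competition and the trait-SD shrinkage
  under filtering are robust at s_E = 0.1.
- β-competition with large β_intra/β_inter strongly inflates richness
  (strong negative density dependence), which makes it *easier* to
  separate from pairwise competition than a narrow β prior would.
- The coalescent treats each species independently; there is no
  migration-coalescent between local and regional pools beyond the
  source-pool absorption, and no parameter estimation (classification
  only).
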