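# Methods

## The clustering substrate

A phenome table has one row per knockout mutant and ten traits in a fixed
order that also indexes the weight vectors: eight categorical traits
(conidia number/morphology, protoperithecia number/morphology, perithecia
number/morphology, ascospore number/morphology) followed by two continuous
traits (basal hyphal growth rate, mm/day; aerial hyphae height, mm).
Abundance traits use the vocabulary {Not Formed, Severely Reduced, Reduced,
Slightly Reduced, Normal, Increased}; morphology traits use {Not Formed,
Abnormal, Normal}. Vocabularies and column names are configurable, but
these defaults match how such collections are scored. Only records with
all ten traits present are clustered; `filter_complete` drops the rest and
logs the counts.

## Continuous-trait bins

The continuous traits are binned against wild-type reference ranges
(growth 75–85 mm/day, aerial height 30–45 mm) into seven severity bins
(Severely Reduced … Normal Low/Average/High … Increased). The published
boundaries are stated to one decimal and leave small gaps
(e.g. 82.5→82.6); values are therefore rounded to one decimal before
comparison and each printed range is treated as inclusive, which closes
every gap on the growth scale. The aerial scale retains one unprinted
interval (29.1–29.9 mm, between "25–29" and "30–35"); it is assigned to
the bin above (Normal Low), so binning is total on [0, ∞). Negative or
non-finite values are rejected.

For the global phenotype classification, a growth defect is any non-Normal
growth bin — including Increased, a convention: faster-than-wild-type
growth is treated as a phenotype, consistent with counting every
non-normal trait value as a defect. An asexual defect is an abnormal
aerial bin or a non-Normal conidial trait; a sexual defect is any
non-Normal value among the six sexual-structure traits. A mutant defective
in several classes contributes to each, so the total global phenotype
count is the sum of the three class counts.

## Ordinal conversion

Only the four abundance traits map credibly onto a severity scale; the
morphology traits do not and are excluded from the numeric pipeline. The
scale is Not Formed 0, Severely Reduced 0.25, Reduced 0.5, Slightly
Reduced 0.75, Normal 1.0, Increased 1.5. The two continuous traits are
z-scored over the analyzed table (mean 0, sample SD 1) before K-means or
Pearson-distance clustering so that mm-scale values and the 0–1.5 scale
are commensurable; the choice is ours — nothing forces a particular
scaling, and z-scoring is the least informative one.

## Dissimilarities

Weighted Gower: d(i,j) = Σₜ wₜ·δₜ(i,j)/Σₜ wₜ with δₜ = |xᵢ−xⱼ|/rangeₜ
(range over the analyzed table, i.e. after completeness filtering) for
continuous traits and 0/1 mismatch for categorical traits. Categorical
traits are nominal even when their labels look ordered — the mismatch is
all-or-nothing. A continuous trait with zero range contributes 0 to the
numerator (its weight stays in the denominator) and warns. Entries lie in
[0, 1]; weights are scale-invariant. The seven presets range from uniform
(`NoWeight`) to `W6` = (1,1,1,1,1,1,1,1,6,6), which gives the two
continuous traits 60% of the total weight.

One-minus-Pearson distance (range [0, 2]) is provided for the converted
numeric pipeline; rows with zero variance have undefined correlation and
raise rather than being silently imputed.

## PAM

PAM is implemented natively so its determinism is fully specified. BUILD
seeds the first medoid as the point minimizing total dissimilarity and
adds each next medoid to maximize the total cost reduction. SWAP evaluates
every (medoid, non-medoid) exchange with exact incremental deltas (the
FastPAM1 decomposition, algebraically identical to naive re-evaluation),
applies the single best-improving swap — ties broken by smallest table
index — and repeats to convergence. The cost trace is recorded and is
non-increasing by construction. PAM is a local search: on a few percent
of tiny random instances the swap-local optimum differs from the global
optimum found by exhaustive medoid enumeration; the reference R
implementation behaves the same way. The suite asserts the true
guarantees (local optimality, monotone cost, exact recovery on separable
instances) and the acceptance script reports the measured match rate
against exhaustive enumeration.

Ward and complete-linkage agglomerative clustering run through
scipy's Lance–Williams implementation; "ward" follows the ward.D2
convention (updates on squared dissimilarities), the variant closest to
what mixed-data practitioners get from standard R tooling, applied to the
(non-Euclidean) Gower matrix as-is. Hierarchical assignments also report
per-cluster medoids and the medoid cost so all methods share one result
type. K-means (scikit-learn, Lloyd, `init="random"`) takes an explicit
seed and restart count; the best of `restarts` runs by within-cluster sum
of squares is returned and empty clusters are relocated to the
worst-fitting points, so results are deterministic given (data, k, seed,
restarts).

## Cluster quality and model selection

Per cluster: for each continuous trait the relative standard deviation,
100·SD/mean with the sample (n−1) SD — the default in the R toolchain
this analysis style comes from; a singleton cluster has RSD 0, and a
non-positive mean (guard 1e−9) is an error. For each categorical trait
the percent consensus: the share of the modal category, ties broken by
vocabulary order and flagged. Run-level per-trait values average clusters
**with equal weight** (not by size). Two composites summarize a run: the
mean of the two continuous per-trait averages and the mean of the eight
categorical per-trait averages. The selection guidelines are ≥3 genes per
cluster, ≤40 clusters, composite RSD strictly below 15% and composite
consensus at least 95%. `weight_scan` tabulates (preset, k) combinations
and flags the lexicographic best (max composite consensus, then min
composite RSD); selection remains the user's call, and both printed-style
per-trait columns are emitted alongside the composites so users can
compare alternative summaries.

`cluster_summary` reports, per cluster and trait, the majority phenotype
with its percentage (continuous traits first pass through the severity
bins); when no phenotype exceeds 50% the cell reads "Varied".

A note on using consensus to pick k: merging distinct planted clusters
sharply lowers consensus, so consensus rises as k approaches the planted
number from below; splitting an already-pure cluster, however, does not
lower it (small fragments have slightly *higher* modal shares), so
consensus alone does not peak at the planted k — it plateaus. That is why
the guidelines cap k and bound cluster size rather than relying on the
composites alone.

## Expression profiles

Rows are standardized to mean 0 and sample SD 2 — the ±2 band gives
comparable relative expression per gene; constant rows cannot be
standardized and are dropped with a warning rather than zero-filled
(zero rows would drag centroids toward the origin). Profiles come from
K-means with 25 random restarts by default (the usual `nstart = 25`
practice; 6–8 profiles genuinely need multiple initializations).

Choosing the profile count: `k_diagnostics` reports, per k, the
within-cluster sum of squares (monotonically non-increasing; elbow left
to the user), the gap statistic with B = 50 uniform reference sets drawn
within the observed per-time-point ranges (the simplest Tibshirani
reference; SE inflated by √(1+1/B); recommended k is the smallest with
gap(k) ≥ gap(k+1) − SE(k+1)) and the Davies–Bouldin index (argmin
recommended). On planted data at noise SD 0.25 all three agree with the
planted count.

`map_profiles` intersects the gene sets of a phenotypic clustering and a
profile assignment, excludes phenotypic clusters with fewer than three
expression-covered genes, and calls a profile *dominant* when it covers at
least 40% of a cluster's covered genes (ties to the smallest profile id).
The run-level report gives the average number of distinct profiles per
cluster and, among clusters with a dominant profile, the share carried by
the modal dominant profile.

## Annotation composition

Composition percentages use cluster size as the denominator; genes absent
from the annotation table count as attribute-false with a warning, so a
sparsely annotated attribute reads as a low percentage rather than a
biased one. The `is_GPCR ⇒ has_TM` implication is validated on input.
MAPK multi-pathway counts tally, per gene, how many of the three target
flags (MAK-1, MAK-2, OS-2) are set. The chromosome goodness-of-fit test
apportions the dataset total by the genome's seven linkage-group
proportions and computes Pearson's X² with 6 degrees of freedom
(upper-tail p); the acceptance script checks it against a multinomial
Monte-Carlo null.

## Synthetic data

Generators are pure functions of (config, seed) via
`numpy.random.default_rng` and their outputs round-trip through the
package's readers.

Phenotypes: each cluster has an archetype — per-trait continuous mean/SD
and a modal categorical label drawn with consensus probability p (else
uniform over the remaining labels). Continuous draws are normal, clipped
at 0 (growth and height are physical). Missingness, when requested, is
uniform per cell. The bundled `collection_like_config` mirrors the
marginal structure of a large curated collection: 1168 mutants in 40
clusters with sizes 5–171 (median 14), p = 0.95 and continuous SD = 5% of
the cluster mean. Archetypes are sampled uniformly (continuous means
within physical ranges: growth 20–100 mm/day, height 5–60 mm) subject to
a minimum pairwise unweighted Gower separation of 0.25, fixed as a design
constant: the separation constraint makes the planted partition
identifiable in principle, so recovery scores measure the algorithm, not
generator luck. What this generator does *not* emulate: correlated
traits within a mutant, archetypes that coincide on most traits, ordinal
structure in the categorical noise, or record-level missingness patterns —
so passing recovery tests demonstrates algorithmic correctness under
separable planted structure, not performance guarantees on real
collections.

Expression: a bank of eight standardized template shapes over [0, 1]
(pulses at different phases, monotone rise, late dip, one full cycle,
plateau-then-fall) with pairwise correlation < 0.8 at 4–12 time points;
gene curves are template + i.i.d. normal noise. Anti-correlated shapes
are deliberately allowed — they are maximally distinguishable — and the
generation-time distinctness check therefore bounds signed correlation
(< 0.9), not magnitude.

Annotations: Bernoulli attributes per gene with global or per-cluster
probabilities; GPCR draws force the TM flag; linkage groups are
multinomial over seven chromosomes with configurable genome proportions.

## Numerical conventions

- Sample SD (n−1) everywhere an SD appears.
- Dissimilarity matrices are symmetrized to remove floating-point drift
  and validated (zero diagonal, non-negativity, symmetry at 1e−12).
- All tie-breaks are deterministic: smallest table index (PAM), first
  appearance (label renumbering), vocabulary order (consensus ties),
  smallest profile id (dominance ties).
- Seeds are explicit parameters of every stochastic operation; repeated
  runs are byte-identical.

## Problem sizes used in the checks

The test suite and acceptance script run at the scales the analysis is
designed for: the full 1168 × 40 collection configuration for PAM
recovery (a single run takes ~2 s), 200 random instances at n ≤ 8 /
k ≤ 3 for the enumeration comparison, 240–320-gene time courses for
expression recovery, and 20 chromosome layouts with 10⁵ Monte-Carlo draws
each for the goodness-of-fit check.

## Known limitations

- PAM's swap neighborhood can terminate off the global optimum (see
  above); for collection-scale data this is the standard behaviour of
  every PAM implementation.
- The gap statistic uses the uniform-over-range reference only; no
  PCA-aligned reference is provided.
- Ward on a non-Euclidean Gower matrix is a convention, not a theorem;
  results are reported as-is.
- Real supplementary data files from published collections are not
  bundled; the pipeline reads their layout via column maps, and all
  bundled inputs are synthetic.
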