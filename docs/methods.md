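# Methods

## Fold estimation

The pipeline's downstream statistics consume only per-gene signed log2
fold changes, so differential expression is estimated as a group-mean
difference rather than a moderated linear model: counts are filtered
(gene kept iff count ≥ `min_count` = 10 in at least one sample),
`log2(count + 1)` transformed, normalized, and summarized as
`mean(treated) − mean(control)`. No variance shrinkage is applied because
no per-gene test statistic is ever formed from the folds — module-level
inference comes entirely from the resampling contrast test, which is
distribution-free over genes.

Normalization methods:

- **quantile** (default): each sample's sorted values are replaced by the
  across-sample mean of sorted values. Ties take the average rank; a
  half-integer rank interpolates between the two adjacent sorted means.
  This makes the value multisets exactly equal across samples on tie-free
  data and approximately equal on integer counts.
- **scale**: samples multiplied to a common median absolute level.
- **tmm**: trimmed mean of M-values on raw counts (30% M-trim, 5% A-trim,
  inverse-variance weights, reference = sample whose upper-quartile count
  fraction is closest to the mean), applied as a log2 library-size offset.
  A sample with all-zero counts has no defined factor and is an error.

"Expressed in a condition" means raw count ≥ 10 in at least one sample of
that condition (the same threshold as the global filter); genes silent in
both conditions are dropped from the fold table.

Fold thresholds follow their verbal definitions: the 2-fold DE call is
inclusive (`|log2FC| ≥ 1`), while "changed by more than 8-fold/10-fold"
selections are strict. Consequently the 10-fold sets always nest inside
the 2-fold sets.

## Module catalog

Ontology edges are child → parent and must be acyclic (a cycle aborts with
one offending edge named). Propagation follows the true-path rule:
`module(C)` contains every gene annotated to `C` or to any descendant,
computed in one topological pass. Categories with empty sets are dropped.
Flat pathway sets (GMT) are merged afterwards. Deduplication unites
entries with identical gene sets — identical observable sets are
statistically indistinguishable — and the united entry's id is its source
ids joined by `|` in lexicographic order, which makes catalogs
order-independent. Deduplication is re-applied after restriction to the
analyzed universe because restriction can create new collisions. Default
size window after restriction: 5–2000 genes; smaller modules make both
tests degenerate and larger ones are uninformative, these limits are
conventional and configurable.

## Contrast test

The statistic for module *M* is the module's mean signed log2 fold minus
the universe mean. Working on the signed log2 scale (not linear fold)
keeps up- and down-regulation symmetric and means the statistic is a
plain difference of means. The two-tailed null draws random gene subsets
of size |M| from the universe without replacement, independently across
draws; p is `(count + 1)/(B + 1)` with B = 20,000 by default, so a finite
null never yields p = 0 and `p ≥ 1/(B+1)` always. When
`C(N, |M|) ≤ 10,000` every subset is enumerated instead and p is exact
(`count/total`, no plus-one correction needed); this path doubles as the
oracle for the Monte-Carlo path in the test suite. Extremeness
comparisons use a `1e-12` absolute slack so that exact ties (e.g. the
module equal to the whole universe) are never lost to float roundoff.

The Monte-Carlo inner loop is a numba-compiled partial Fisher–Yates
shuffle: each draw performs |M| swaps into a persistent index permutation
and accumulates the subset sum, giving O(B·|M|) work per module
independent of universe size. Each module receives an independent derived
seed (from the run seed and the module's rank in sorted order), so
results do not depend on catalog iteration order and runs are exactly
reproducible.

## Multiple-testing control

Benjamini–Hochberg adjustment delegates to statsmodels. Storey–Tibshirani
q-values use `π₀(λ) = #{p > λ}/(m(1 − λ))` on the grid λ = 0.05…0.90
(step 0.05), smoothed by a least-squares cubic polynomial evaluated at
the largest λ and clamped to (0, 1]. A cubic polynomial was chosen as the
smoother because it is deterministic, dependency-light, and with 18 grid
points behaves like the conventional 3-df smoothing spline. The q-value
step-up is evaluated in the same floating-point order as the BH step-up,
so forcing π₀ = 1 reproduces BH bit-for-bit — a property the test suite
asserts.

π₀ estimation is a large-scale procedure: with few tests the tail of
`π₀(λ)` is noise-dominated and the extrapolation can collapse toward 0,
which would *deflate* q-values below their p-values. The estimator is
therefore only engaged at ≥ 100 p-values; below that π₀ = 1 is used
(logged), making the q-values coincide with BH — conservative but
calibrated.

Module classification: induced iff `contrast_q < 0.10` and contrast > 0,
inhibited with contrast < 0. The secondary regime (p < 0.01, q < 0.15)
is exposed as configuration.

## Networks

Edge scores are combined-confidence values in [0, 1]; any score > 1 in an
input flags the raw 0–1000 integer scale and all scores are divided by
1000. The stringency filter is strict (`S > threshold`), self-loops are
dropped, and duplicate pairs keep the highest score. Node selection for
the induced and inhibited networks (built separately) defaults to the
strict fold cutoff (> 8-fold); a top-quantile selector (default top
quarter by |log2FC|) is available because the two rules coincide only on
data whose fold distribution happens to put the cutoff at that quantile.

Hubs are nodes with degree strictly greater than 5. Clustering embeds
nodes by the first k eigenvectors of the symmetric-normalized Laplacian
`I − D^{−1/2} A D^{−1/2}` built from the score-weighted adjacency
(isolated nodes get zero rows), unit-normalizes rows, and runs k-means
with k-means++ initialization, 20 restarts and a fixed seed. On disjoint
cliques this recovers the components exactly, which the suite uses as the
oracle. k defaults to the number of connected components with ≥ 3 nodes.
Cluster annotation runs the hypergeometric test of every catalog module
against the cluster members, BH-adjusts within the cluster, and reports
adjusted p < 0.05.

## Cross-study concordance

Classes: `silent` iff the gene carries no fold in this study (absent from
the fold table or from the count universe); otherwise `same`/`opposite`
by fold-sign agreement. An exactly zero fold here has no direction: such
genes are classed `none` and excluded from the binomial test and the
correlation, since exact zeros have measure zero on real data and the
three-class scheme leaves them undefined. The binomial test is exact and
two-sided (`2·min(tail, ½)`, clamped to 1) for the larger direction count
against p = 0.5 on same+opposite trials; a variant that pools silent
genes with the discordant arm is also computed in the summary, because
"changed in the same direction" prevalence can be read either way and the
two readings differ by many orders of magnitude on unbalanced partitions.
Correlation is Pearson's r over same+opposite genes only (silent genes
have no second fold).

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
with ground truth recorded for every planted feature:

- **Counts**: negative binomial with mean μ and variance μ + αμ²
  (α = 0.1 by default, a typical bulk RNA-seq dispersion), baseline log2
  means uniform on (3, 10), two conditions × 3 replicates. Planted
  modules claim disjoint random gene sets and their log2 effect is split
  symmetrically (±effect/2 per condition) so library sizes stay
  comparable and normalization is not confounded. Default planting in the
  pipeline simulation: 20 up and 4 down modules of 50 genes at |effect| 2
  — the recovery conditions the acceptance checks measure — plus one
  60-gene module per direction at |effect| 4 so that the strict 8-fold
  network selection has a realistically strong deregulated gene set to
  work on.
- **Ontology**: a layered DAG with occasional double parents (diamonds)
  and, when more than one leaf exists, a pass-through category duplicating
  one leaf's propagated set so deduplication always has work to do.
- **Interaction network**: planted partition over near-equal blocks;
  within-block edges score uniform on (0.91, 1.0), between-block on
  (0.40, 0.90), so stringency 0.9 separates the planted structure.
- **Cross-study table**: class counts realized exactly via
  largest-remainder rounding of the requested fractions (defaults
  21/123, 42/123, 60/123). In the pipeline the reference list is aligned
  to the actual fold table (silent rows prefer genes filtered as silent in
  both conditions) so the end-to-end classification reproduces the
  planted partition.

One integer seed drives everything; each generator derives an independent
stream from (seed, stream-name) so adding a generator never perturbs
another, and identical seeds reproduce outputs byte-for-byte.

What the synthetic data does **not** emulate: read-level error and
mapping ambiguity, correlated gene-gene noise, GC/length biases,
overlapping or hierarchically nested planted modules, scale-free degree
structure in the interaction network, and batch effects. Passing tests
therefore demonstrate correctness and calibration of the statistics under
the assumed generative model, not robustness to those real-data
pathologies.

## Problem sizes and numerical choices

The characterization experiments use 2,000 resamplings per module
(p-resolution 1/2001, ample for thresholds at 0.05/0.10) over catalogs of
a few hundred modules in a 10,000-gene universe; the API default stays at
20,000 resamplings. The calibration experiment tests 2,000 random modules
of sizes 10–100 on a null simulation; the recovery experiment adds 200
random null modules alongside the planted ones to measure the false-call
rate. Exhaustive enumeration bounds (10,000 subsets), the 1e-12 tie
slack, and seed derivations are as described above.

## Known limitations

- The group-mean fold estimator ignores per-gene variance; genes with a
  single extreme replicate can pass fold thresholds that a moderated test
  would reject. Module-level inference is insulated by the resampling
  null, which inherits the empirical fold distribution.
- Quantile normalization slightly attenuates planted effects when a large
  fraction of the transcriptome is planted in one direction (it forces
  identical value distributions across samples); at the default planting
  density (~13% of genes, mostly balanced) the attenuation is well under
  the detection margin.
- The contrast test's resampling null is shared-universe: module p-values
  are mildly dependent across overlapping modules, as in any
  competitive gene-set test.
- k-means on the spectral embedding can split large sparse components
  arbitrarily when k exceeds the number of natural blocks; k is
  user-controllable for that reason.
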