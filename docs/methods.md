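# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the limits of what the test suite demonstrates.

## Study design emulated by the generator

Two wheat cultivars — one heat-tolerant, one heat-sensitive — exposed to
25, 30 and 35 °C, with six biological replicates per genotype × temperature
cell for the metabolome and three for the transcriptome (RNA-seq in
triplicate). Temperature is encoded as an ordinal dose d ∈ {0, 1, 2}: the
simplest monotone encoding consistent with a graded-stress design.

**Metabolome.** Feature log2 abundances are Gaussian around a per-feature
baseline (baseline ~ N(10, 2²) on the log2 scale, i.e. log-normal
abundances, the standard skewed model for LC-MS intensities), with noise
SD 0.5 (log2). Three disjoint marker sets respond linearly to dose with
slope `marker_effect` (default 2.0 log2-fold per step): *shared* markers in
both genotypes, *tolerant-* and *sensitive-specific* markers only in
theirs. Defaults: 500 features, 10 shared + 5 + 5 specific markers. The
feature count is scaled down ~7× from the thousands of LC-MS features a
real study measures; the marker-to-noise ratio is chosen so that recovery
is demanding but attainable at n = 6/class.

**Transcriptome.** Each planted module m has a latent factor z_m per
sample, standardized to unit sample variance so the planted module strength
is exactly controlled rather than subject to n = 18 sampling luck. Member
genes respond affinely on the log2 scale (slope magnitude U(0.8, 1.2), 20%
negative — the unsigned network treats anti-correlated members
identically), background genes are flat. Counts are negative-binomial with
var = μ + α·μ² (α = 0.1, a typical bulk RNA-seq overdispersion; base mean
≈ 200 counts). Defaults: 1000 genes, 4 modules of 60/80/100/120.

**Traits.** For each module one non-marker metabolite is designated its
trait. On the log2 scale the trait is `r·z + sqrt(1−r²)·ε` with ε
orthogonalized against z in-sample, so the planted latent–trait Pearson
correlation equals `module_trait_r` (default 0.7) exactly; what remains
stochastic downstream is the eigengene's estimation of z and the
replicate-alignment jitter. `embed_trait_metabolites` writes the trait
values into the metabolome (replicates mapped cyclically onto the
transcriptome grid, log2 jitter SD 0.1).

What the generator does **not** emulate: chromatographic artifacts, batch
effects, missing-at-random dropout, library-size variation beyond NB noise,
read-level data. Passing recovery tests therefore demonstrates the
*logic* of the pipeline under its stated noise model, not robustness to
real-data pathologies.

## Random-forest importance and consistency

Per genotype a bagged ensemble (default 1000 trees; CART trees with
floor(√p) candidate variables per split) classifies temperature. The
bootstrap is explicit, so out-of-bag (OOB) sets are known per tree. MDA for
feature j: for each tree whose splits use j, permute j within the tree's
OOB samples and record the accuracy drop; sum over trees, divide by the
total tree count, average over 10 permutation repeats. This is the classic
unscaled permutation importance; at one probe dataset it agrees with R's
`randomForest` (ntree = 1000, `scale=FALSE`) at Pearson 0.96 with 18/20
top-20 overlap. Only trees containing j need re-prediction, which makes
exact OOB MDA cheap at 1000 trees.

Consistency of feature j between the two models:
`1 − |ñ_A(j) − ñ_B(j)|`, where ñ is the model's MDA min-max normalized to
[0, 1] after clipping negatives to zero (negative permutation importance
is noise). Categorization: "high importance" = MDA at or above the 80th
within-model percentile (inclusive); shared = high in both AND consistency
≥ 0.8; A-/B-favored = high in exactly one; uninformative = the rest. The
partition is exhaustive by construction.

A known limit: with several interchangeable (correlated) strong markers,
each forest splits importance among them stochastically, so the min-max
normalized values fluctuate between independently fitted forests and a
~30% fraction of genuinely shared markers falls below consistency 0.8 at
these defaults; R's randomForest shows the same behavior. Per-seed
categorization accuracy on planted markers is therefore ≈ 0.7–0.8, not 1.

Rank concordance is tie-corrected Spearman over the common feature set.
Note that with many uninformative features the global ρ is dominated by
their random ranks: two models can both rank every informative marker at
the top and still show ρ ≈ 0.1 on thousands of features — which is exactly
why directional tests of concordance use compact marker-rich panels
(p = 40, 20 markers), where the block structure makes the expected
direction analyzable (ρ ≈ 0.75 shared vs ρ ≈ −0.1 disjoint).

## PLS-DA, VIP and validation

Features are standardized to unit variance (zero-variance features are
excluded with a warning); the response is the centered one-hot class
matrix (a single column for two classes). The fit is NIPALS PLS
(scikit-learn's `PLSRegression`); VIP uses the weighted-sum-of-squares
formula over components with SS_a = (tᵀt)·Σ_m q²_ma, which guarantees
mean(VIP²) = 1 — checked to 1e-8 on every construction. Q² comes from
stratified 7-fold cross-validation (1 − PRESS/TSS). Permutation p-values
use the (b+1)/(B+1) estimator over B = 200 label permutations (bounded
below by 1/(B+1), so never zero). The DAM rule takes the stated
inequalities strictly: VIP > 1.0 AND p < 0.05.

OPLS-DA's orthogonal filtering is not implemented; for a single binary
response the predictive subspace is the same and VIP ranking differences
are immaterial at this scale. This remains an open interpretation.

## DEG calling

No canonical method was mandated, so the caller is deliberately plain and
recorded in its output metadata: median-of-ratios size factors
(geometric-mean reference over all-positive genes, library-size fallback),
Welch statistic on log2(normalized + 1) with a normal-approximation
p-value, Benjamini–Hochberg FDR, rule |log2FC| ≥ 1 and FDR < 0.05. Power
note: a gene with a true 2-fold change has its estimated log2FC centered
exactly on the threshold 1, so the default rule recovers at most ~half of
exactly-2-fold genes regardless of noise; recovery tests use a 1.4-fold
threshold at low dispersion, and the defaults are exercised for null
calibration (raw p ≈ 5%, ≈ 0 after FDR).

## Co-expression modules

Unsigned convention throughout: a_ij = |cor|^β with β = 9 (the configured
power; a scale-free-fit scan over β = 1…16 is reported alongside),
unsigned TOM, dissimilarity 1 − TOM, average-linkage hierarchical
clustering. The branch cut is static: by default the tree is cut at the
midpoint of the largest gap among the upper half of merge heights. The
rationale: within-module merges complete low in the dendrogram while the
unstructured background merges in a dense plateau near the top, so the
largest upper gap separates the regimes; a fixed quantile of merge heights
lands inside the background plateau and collapses everything into one
module. On null data the gap rule leaves all genes grey. Clusters below
`min_module_size` = 50 genes are relabeled grey. Eigengenes are the first
right-singular vector of the module's gene-standardized expression,
unit-norm, sign-oriented positively with the module mean profile. Modules
whose eigengene dissimilarity (1 − Pearson) clusters below 0.25 are merged
iteratively to a fixed point. Module–trait correlation is Pearson with
two-sided Student-t p on n − 2 df; near-constant profiles correlate 0 with
a warning. Metabolome traits (6 replicates) are aligned to transcriptome
samples (3 replicates) by (genotype, temperature, replicate) keys, with
within-cell averaging and broadcast when keys do not match.

## Biomarker cascade

Candidates are the top-k (default 100) features by the designated model's
importance (default: the tolerant cultivar's model; which model the
original analysis used is ambiguous, so it is a parameter). The filter
keeps a candidate if its mean abundance across stressed samples
(30 + 35 °C) is strictly higher in the tolerant genotype, OR a one-sided
Welch test (tolerant > sensitive at 35 °C) rejects at 0.05 — the
directional claim warrants a directional test. Both clauses are recorded
per marker. Because the higher-mean clause accepts ~half of all
null-difference features by symmetry, a candidate list much larger than
the true marker set necessarily dilutes the panel; recovery is therefore
quantified at candidate depth k = 15 (the planted tolerant-relevant
scale), where the panel's Jaccard similarity to the planted
shared + tolerant-specific markers is ≈ 0.7.

## Enrichment, hubs, convergence

Over-representation is the hypergeometric upper tail P[X ≥ k] with BH
adjustment; the universe defaults to all measured genes and query ids
outside it are excluded with a warning. Hubs are the top-50 nodes by degree
within a module's interaction subgraph (ties: weighted degree, then id);
interaction edges are always consumed from a user or synthetic edge list,
never fetched from a database. kIM(i) sums a gene's adjacency to its module
peers. The convergence table scores each annotation term by three boolean
evidence streams: covers a final biomarker; enriched (FDR < 0.05) in a
module; that module's eigengene correlates (p < 0.05) with a panel trait.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds (`numpy` Generators; no
global state). The pipeline fans a single base seed into per-stage seeds
via `SeedSequence([base, stage_index])`. Identical config + seed gives
byte-identical output files. Test problem sizes (500-feature metabolome,
1000-gene transcriptome, 25–100 seed replicates for medians) are chosen so
the full suite runs in about ten minutes on one CPU while keeping every
recovery margin non-trivial; the acceptance script reruns the main
computations in about two minutes.

## Known limitations

- Consistency and categorization thresholds are declared interpretations;
  the original cutoffs are not recoverable from the source analysis.
- The MDA scaling question (raw vs SD-scaled) is resolved as raw/unscaled.
- The static branch cut is a deliberate simplification of dynamic
  tree-cutting; it recovers well-separated planted modules but will not
  reproduce dynamic-hybrid behavior on nested or overlapping modules.
- Synthetic module counts are what the generator plants; no claim is made
  that synthetic runs reproduce the real dataset's 14 modules.
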