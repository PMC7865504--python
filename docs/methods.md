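# Methods

`canetx` compares cancer and control omics profiles (metabolite abundances
or gene expression) through statistical association networks and pathway
analysis. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Data preparation

Input tables are samples × features abundance matrices with per-sample
cancer/control labels. The fixed preparation order is: alias
harmonization → duplicate consolidation → missingness filter → kNN
imputation → natural-log transform.

- **Alias harmonization.** Feature ids may carry several
  namespace-qualified identifiers (`kegg:C00031;hmdb:HMDB0000122`). Each
  matching alias votes for a canonical name; majority wins, ties break to
  the lexicographically smallest canonical name so renaming is
  deterministic and auditable. Unmatched features keep their original
  name. No live database lookups: alias tables are user-supplied TSV.
- **Missingness filter.** Features with strictly more than 10% missing
  cells (`max_frac=0.10`) are removed before imputation; exactly 10% is
  retained.
- **kNN imputation** (`k=10`). Neighbours are other *features*, ranked by
  Euclidean distance over samples observed in both (scaled by the shared
  count); candidates sharing fewer than 3 observed samples are excluded.
  A missing cell becomes the mean of the k nearest neighbours observed in
  that sample; with no eligible neighbour, the feature mean. The per-count
  scaling and the fallback are our choices — they make the distance
  comparable across unequal overlaps and guarantee completion.
- **Log transform.** Natural log; the base only rescales downstream linear
  statistics. Non-positive values are an error unless an explicit offset
  is configured; no silent pseudo-counts.
- **Gene variance pre-filter.** For transcriptomics, only genes present in
  every data set whose log-variance exceeds the pooled mean + 1 SD of all
  per-data-set log-variances are kept (a gene's eligibility uses the mean
  of its per-data-set log-variances). Pooling over the concatenated
  log-variances (rather than averaging per data set first) was an open
  choice; pooled is simpler and symmetric in the data sets.

## Shrinkage Gaussian graphical model

Partial correlations are estimated from the shrunk correlation matrix
R* = λI + (1−λ)R, with the analytic intensity

λ* = Σ_{i≠j} Var̂(r_ij) / Σ_{i≠j} r_ij²,  clamped to [0, 1],

using the unbiased variance estimate of each sample correlation
(standardized columns, denominator n−1). The partial correlations are
ρ_ij = −ω_ij/√(ω_ii ω_jj), Ω = (R*)⁻¹, unit diagonal. The identity target
on the correlation scale is the conventional default for this estimator.
When p ≥ n a floor λ ≥ 1e−8 guarantees invertibility. λ is recomputed on
every resampled subset rather than reused from the full data — the
subsample is what the iteration actually sees.

## PCLRC network inference

The Probabilistic Context Likelihood of Relatedness on Correlations wraps
the GGM in a resampling loop. Per iteration: draw ⌊frac·n⌋ samples
*without replacement* (a fraction of the samples implies subsampling, not
bootstrap), estimate partial correlations, apply CLR background
correction — z_i(j) = max(0, (|s_ij|−μ_i)/σ_i) over row i, pair score
√(z_i(j)² + z_j(i)²) — and mark the top `rank_thr` fraction of off-diagonal
pairs by score, including all pairs tied with the cutoff score
(deterministic). Marking frequencies over `niter` iterations form the
probability matrix P, and the association network keeps the *full-data*
partial correlation r_ij wherever p_ij ≥ `prob_thr` (inclusive boundary),
zero otherwise.

Defaults: `niter=1000`, `frac=0.75`, `rank_thr=0.3`, `prob_thr=0.95` for
metabolite networks; `niter=100`, `prob_thr=0.99` for gene networks
(`GENE_DEFAULTS`). All resampling is driven by one seeded generator;
identical seeds give bit-identical probability matrices.

## Node connectivity and differential connectivity

Node connectivity is χ_i = Σ_j |r_ij| over the thresholded weights —
equivalently the row sum of |weights| with the implicit unit diagonal,
minus 1. The differential connectivity of node i between matched networks
is Δ_i = χ_i(cancer) − χ_i(control).

Significance uses a column-permutation null: every feature column of each
group matrix is permuted independently (destroying inter-feature
association, preserving marginals and group sizes — group labels are never
shuffled), both networks are re-inferred, and the permuted Δ_i,k recorded.
The empirical p-value is p_i = (1 + #{|Δ_i,k| > |Δ_i|})/k, BH-adjusted
across nodes. The permuted deltas are folded to absolute values by
default (`null="signed"` compares them as-is); with symmetric nulls the
two differ little, and the folded version is the cleaner two-sided test.
Defaults: k = 1000 for metabolite networks, k = 100 for gene networks.
Re-inferring 2k networks at full `niter` is not desk-scale, so
permutation-time inference uses `perm_niter=50` PCLRC iterations (the
observed networks keep the full budget); both k and perm_niter are carried
in the result object.

**Calibration caveat.** The permutation null encodes *no association at
all*. Under that exchangeability null the test is exact: on independent
features (p=20, n=60 per group, k=200) the measured type-I error at
α=0.05 is 0.050. When the two groups share a *nonempty* association
structure, however, sampling noise in the two network estimates makes
|Δ_i| exceed the no-association null for most nodes (measured 65%
rejection under a shared sparse GGM): the test answers "is this node's
connectivity difference larger than expected with no associations?", not
"are the two dependence structures equal?". This is a property of the
method itself and explains why differential-connectivity screens of real
case/control panels flag large fractions of features.

## Topology profile

Twelve network-level measures summarise one association network; all are
computed on the unweighted skeleton (edge ⇔ nonzero weight) except mean
connectivity (mean χ_i, weighted):

nodes; edges; mean connectivity; mean degree = 2E/(N(N−1)) (edge
density); mean Wasserman–Faust closeness ((r/(N−1))·(r/Σd), isolated
nodes 0); mean shortest-path betweenness normalised by (N−1)(N−2)/2;
diameter (max eccentricity in the largest component); mean minimal
distance (mean shortest path over connected pairs); mean PageRank
(damping 0.85 — identically 1/N, kept for table compatibility); hub nodes
(count of nodes with raw degree strictly above the mean degree; a
mean+k·SD rule is exposed); Freeman degree centralization
Σ(d_max−d_i)/((N−1)(N−2)); transitivity (3·triangles/triples). Every
metric is validated against independent brute-force implementations on
all 1252 graphs with ≤7 nodes. Rounding to 3 decimals happens only at the
presentation layer.

## Moderated t differential abundance/expression

Per feature, the two-group contrast on log-scale data with empirical-Bayes
variance shrinkage: residual variances s_g² (d_g df) are shrunk toward a
prior s0² with weight d0, s̃_g² = (d0·s0² + d_g·s_g²)/(d0+d_g), and
t = logFC/(s̃_g·√(1/n_a+1/n_b)) has d0+d_g df. The prior (d0, s0²) comes
from closed-form moment matching of the log residual variances on the
digamma/trigamma scale, with Newton inversion of the trigamma and an
infinite-d0 fallback when the log-variances show no excess spread (the
degenerate all-equal case returns the common value exactly, so
moderation is a no-op there). F = t² and the log-odds B (prior proportion
0.01, contrast-prior standard deviations clamped to [0.1, 4]) are
included for completeness. The implementation reproduces the Bioconductor
reference implementation to ~1e−12 on a frozen fixture and collapses to
the classical pooled t when d0 is forced to 0. The workflow here is the
Gaussian linear-model moderated t appropriate for continuous log-scale
data — not count-based negative-binomial machinery. BH adjustment is the
default for metabolite panels; Bonferroni for genome-wide gene panels.

## Pathway enrichment and impact

Over-representation is the hypergeometric upper tail of the observed hit
count among a pathway's members restricted to the tested universe
(equivalent to one-sided Fisher), BH-adjusted across pathways. Pathway
impact weights members by relative betweenness centrality in the pathway
graph and reports the fraction of total centrality mass carried by hits,
so impact ∈ [0, 1]. Nodes with zero betweenness (leaves) would be
invisible under pure betweenness; by default they receive a small floor
weight proportional to degree, scaled by the smallest positive
betweenness in the graph (`zero_floor="none"` disables this). Joint
gene+metabolite analysis pools hits and universes over both kinds
(identifiers must be kind-prefixed) and runs the same machinery on the
pooled pathway. Pathway content is user-supplied (GMT memberships, SIF
graphs); nothing is bundled beyond a generated toy set for tests.

## Cross-analysis comparison

Impact or topology matrices (analyses × variables) are compared by PCA on
unit-variance-scaled columns (SVD; component signs fixed so the
largest-|loading| entry is positive), UPGMA clustering of the first three
component scores under Euclidean distance, and pairwise dendrogram
agreement via the cophenetic correlation. Duplicate labels are collapsed
to centroids before clustering; trees are pruned to the common leaf set
by rebuilding the induced subtree from the restricted cophenetic matrix
(exact, because cophenetic distances are ultrametric). The correlation is
Pearson's over the leaf-pair cophenetic distances; it is 1 under affine
height transforms and below 1 under merely rank-preserving ones.

**Topology classification.** How well a single topology measure separates
cancer from control networks is quantified by leave-one-out
cross-validated univariate logistic regression (intercept + measure,
unregularised IRLS, 100-iteration cap, 1e−8 deviance tolerance; under
perfect separation the last iterate's ordering is used). The default AUC
estimator is **leave-pair-out**: every cancer/control pair is held out
together and scored by the one model fitted on the rest, and the AUC is
the fraction of correctly ordered pairs (ties 0.5). Ranking held-out
probabilities that come from *different* leave-one-out refits
(`method="single"`, also exposed) suffers a well-known pessimistic bias
for weakly informative measures — a weak feature's AUC can drop far below
its resubstitution value, even below 0.5 — whereas leave-pair-out is the
standard nearly unbiased cross-validated AUC for small samples and stays
within 0.02 of the raw Mann–Whitney AUC on the packaged tables. The 95%
interval is DeLong's normal approximation; with n = 16–28 networks it is
wide, and AUC point estimates — not p-values — are the meaningful
comparison surface at this sample size.

## Synthetic data generator

`make_ggm_pair` emulates the latent structure the pipeline assumes:

- **Control precision**: Erdős–Rényi skeleton (default `edge_prob=0.15`)
  with partial correlations of magnitude U(0.2, 0.4) and random sign;
  positive definiteness by diagonal loading to minimum eigenvalue 0.1,
  then renormalisation to unit diagonal.
- **Planted differential connectivity** (`dc_frac`): the planted nodes are
  the control skeleton's highest-degree (hub) nodes; every edge incident
  to them is moved to a uniformly random pair among the remaining nodes.
  Hubs therefore lose their connectivity in the cancer network — a large,
  directional effect. Partner-preserving rewiring would leave node degree
  (hence connectivity) unchanged and plant nothing detectable. Note the
  nodes *receiving* the moved edges genuinely change connectivity too;
  recovery is therefore scored by the signed connectivity loss −Δ.
- **Planted differential abundance** (`de_frac`, `delta`): a log-scale
  mean shift δ on randomly chosen features in the cancer group. The
  latent covariance is standardised to unit marginal variance (partial
  correlations are scale-invariant), so δ is an effect size in SD units.
- Latent normals are exponentiated to log-normal abundances, exercising
  the log-transform stage; MCAR masking and toy pathway sets (enriched
  pathways over-sampled from a hit list, random connected member graphs)
  are generated separately. Everything is bit-reproducible given a seed.

What the generator does *not* emulate: platform batch effects, missing-
not-at-random patterns, heavy-tailed or zero-inflated abundances, and the
heterogeneous metabolite panels of real multi-study collections. Passing
benchmarks therefore demonstrate correctness of the machinery under its
own assumptions, not robustness to those real-data complications.

## Benchmark scales

The packaged benchmarks run on one CPU in minutes: permutation
calibration at p=20 features, n=60 per group, k=200 permutations with
perm_niter=50; hub-recovery at p=30, n=100 per group over 5 seeds;
differential-abundance power at p=50, n=30 per group, δ=1. Measured
results: type-I 0.050 under the exchangeability null for the permutation
test and within exact-binomial 99% bounds for the moderated t; planted-hub
recovery AUC ≈ 0.99; planted mean-shift power ≥ 0.9 at BH 0.05.

## Known limitations

- Edge selection follows the probability threshold of the resampling
  wrapper; no local-fdr model selection on the partial correlations.
- The permutation test's null is independence, with the calibration
  caveat above.
- Closeness/betweenness are unweighted; no community detection.
- Gene networks at genome scale are expensive: the variance pre-filter is
  the intended workflow, and `perm_niter` bounds permutation cost.
- The hub-node and centralization conventions were fixed against the
  packaged topology tables where internally consistent; printed tables
  from other sources may follow different normalisations.
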