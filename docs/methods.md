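# Methods

This note documents the statistical models behind `gutweb`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Contaminant screening

**Model.** A reagent contaminant contributes an approximately fixed number
of molecules per library, so in samples where it occurs its relative
abundance f satisfies log f ≈ c − log(DNA concentration). For each feature
occurring in at least 5 non-NTC samples we fit, by least squares over the
occupied samples, (i) the contaminant model with the slope of log f on
log-concentration fixed at −1 and (ii) a flat model with slope 0. Both
models spend one parameter, so the residual sums of squares are compared as
an F ratio with (k−1, k−1) degrees of freedom over the k occupied samples;
the score is the left-tail probability — near 0 when the contaminant model
fits much better, near 1 for concentration-independent features. Features
in fewer than 5 samples are unscored and never flagged: two one-parameter
fits on fewer points are degenerate.

**Threshold rule.** Features with score < t are flagged at each grid value
t ∈ {0.05, 0.15, …, 0.95}, and two removal curves are computed: the
percentage of all NTC sequences and of all sample sequences carried by the
flagged set. The default (marginal) selection rule walks the grid and keeps
the last value at which the step to the next grid value still removes more
from NTC than from sample libraries, requiring at least 10 % total NTC
removal; the final grid value inherits the last step's comparison. The
sentence defining this rule in the source methodology is grammatically
ambiguous; the alternative (cumulative) reading — last t with cumulative
NTC removal exceeding cumulative sample removal — is available as
`sweep_mode="cumulative"`. When no grid value qualifies the conventional
default 0.1 is used, with a loud warning. On planted-contaminant data the
score distribution is sharply bimodal (true contaminants ≈ 0, everything
else ≫ 0.5), the curves saturate at the first grid value, and the rule
falls back — which still flags exactly the planted set.

## Count model of the generator

Counts are generated by normal-to-anything (NorTA): a latent multivariate
normal with correlation matrix derived from a planted sparse precision
matrix is pushed through the standard-normal CDF and then through the
quantile function of per-feature zero-inflated negative binomial (ZINB)
margins. The Gaussian copula is chosen over Dirichlet-multinomial because
the inference stage assumes a latent Gaussian graphical model, making
recovery a well-posed target rather than a model-mismatch exercise.

* **Interaction graph.** Band, modular (equal-size modules, edges sampled
  uniformly within modules) or scale-free support; off-diagonal precision
  entries are −sign · 0.3 for an edge of a given association sign (80 %
  positive by default, matching the overwhelmingly positive edge fractions
  reported for real gut networks), and the diagonal is boosted until the
  minimum eigenvalue is ≥ 0.05. Boosting caps the realized partial
  correlations near 0.27–0.32 regardless of the nominal entry.
* **Margins.** Feature means are log-normal (median 50, log-sd 1);
  dispersion is the overdispersion coefficient α in Var = μ(1 + αμ) with
  α = 0.5 (i.e. negative-binomial shape 2 — the alternative reading,
  shape 0.5, gives margins so noisy that no dependence survives);
  zero-inflation is 0.3. All are overridable.
* **Library depths.** Rows are multinomially resampled to log-normal depths
  around `depth_mean` (default 10,000, the common rarefaction target).
* **Host/geography structure.** Host groups are drawn at the survey's
  realistic frog:lizard:salamander proportions (16:35:90) unless
  `balanced_groups=True` (used by the power-study preset, where balanced
  designs are the convention); each group multiplies the ZINB mean of its
  own 10 % feature subset by the group-effect multiplier (default 3).
* **Contamination.** Contaminant features are replaced by Poisson counts
  with expectation strength · depth / (concentration · 50); appended NTC
  libraries (nominal concentration 0.1 ng/µL) carry the contaminants plus
  Poisson(0.2) carry-over noise.
* **Trees.** Pure-birth (Yule) topologies with iid exponential branch
  lengths; not ultrametric.

**What the generator does not emulate:** taxonomic assignment error,
chimeras, sequencing error at the read level, phylogenetic correlation
between margins, batch effects, or overdispersion heterogeneity across
samples. Passing the recovery tests therefore demonstrates correctness of
the estimators under the assumed latent-Gaussian model, not performance on
arbitrary real data.

A caveat worth knowing: the clr transform couples even independent features
through the shared row mean. Simulating a 60-feature community with *no*
planted edges, the null distribution of pairwise clr correlations at
n = 500 has a 99th percentile near |r| ≈ 0.12, concentrated among pairs of
low-log-variance features. This closure effect, not sampling noise, is the
main source of stable false edges in network recovery.

## Network inference

clr uses pseudocount 1 (the convention for count data; pseudocount 0 is
exact-scale-invariant and allowed on positive tables). Neighborhood
selection standardizes columns to zero mean and unit variance (ddof 0), so
the null condition "no edges at λ ≥ max |off-diagonal correlation|" holds
exactly, and solves each per-node lasso by coordinate descent along a
30-point log-spaced path from λ_max down to λ_max/100. Edges are
OR-symmetrized; the weight is the mean of the nonzero directed
coefficients, with opposite-sign conflicts resolved by magnitude and
counted. StARS draws 20 subsamples of size min(⌊10√n⌋, ⌊0.8 n⌋) without
replacement, measures per-penalty instability as the mean over all feature
pairs of 2θ(1−θ), monotonizes it by a running supremum from the sparse end,
and selects the densest penalty whose monotonized instability stays ≤ 0.05
(the standard StARS rule; a literal "sparsest penalty" reading would always
return the empty graph). The final network is refit on the full data at the
selected penalty.

**Expected operating characteristics.** At n = 150 with 60 features in 6
modules of within-module edge density 1/3, the selected networks are
somewhat denser than truth: across seeds, recall ≈ 0.6–0.8 and precision
≈ 0.5–0.7 (mean ≈ 0.63). Two mechanisms bound precision here and are not
implementation artifacts: inside dense modules the lasso irrepresentable
condition fails, so stability selection stably admits two-hop module-mates;
and clr closure correlations (above) are systematic, hence stable. The same
estimator reaches precision 0.84 at n = 300 and 0.89 at n = 600 — n = 150
is simply below the precision phase transition for this graph family. On
latent Gaussian data with no count layer at all, precision at n = 150 is
0.65–0.69, so no choice of margins can do materially better.

## Topology

Module detection (Clauset–Newman–Moore greedy modularity agglomeration),
betweenness and shortest paths run on the unweighted graph, because edge
weights are signed and modularity/shortest paths are undefined for negative
weights; the sign layer is kept for reporting (e.g. the percentage of
negative edges). Q is reported as Σ_c (e_cc − a_c²). Zi uses the
within-module degree z-score with zi = 0 when the module's within-degree
standard deviation is 0 (so singleton modules classify as peripherals); Pi
is the participation coefficient 1 − Σ_c (k_ic/k_i)², 0 for isolated nodes.
Role thresholds (2.5, 0.62) follow the established keystone framework and
are configurable. Hub subnetworks take the ⌈0.30 n⌉ highest-degree nodes,
breaking ties by betweenness and then node id.

## Indicator power

IP = √(a·b) with a and b the positive and negative predictive power from
the 2×2 presence/absence contingency. IP is undefined (not 0) when the
indicator is constant across samples, and undefined values are excluded
from all means with exclusion counts reported; a ubiquitous *target* gives
b = 0 and hence IP = 0, since an always-present taxon carries no negative
indication. TIP for a target is the mean IP over the indicator assemblage —
this satisfies both directions in which the quantity is informally
described. Pearson correlations for the heatmap use (rarefied) abundances,
not presence/absence, matching the split between the two figure panels the
analysis feeds; rows and columns are ordered by complete-linkage clustering
on Euclidean distances between correlation-profile vectors.

## Community ecology

PERMANOVA partitions the Gower-centered matrix by hat matrices of the
sequential (type I) model in entry order — host, geography, interaction —
matching the reporting convention of the adonis function; term degrees of
freedom come from design-matrix rank increments, so empty cells of
unbalanced crossed designs are dropped implicitly. Significance uses free
permutation of sample labels with the add-one estimator
p = (1 + #{F* ≥ F})/(1 + n_perm) (999 permutations by default, so the
smallest attainable p is 0.001); F ties are counted as exceedances at
relative tolerance 1e-9, which keeps the Monte-Carlo p consistent with
exact enumeration on tied null distributions. The dispersion test embeds
samples by PCoA keeping negative-eigenvalue axes, measures each sample's
distance to its group's spatial median (Weiszfeld iteration; centroid
optional) as real-part-squared minus imaginary-part-squared floored at 0,
and permutes group labels over the fixed distances. PCoA reports all
eigenvalues and omits non-positive axes. Patristic distances sum branch
lengths along tip-to-tip paths; trees must carry a length on every
non-root edge.

## Numerical details and degenerate inputs

* Rarefaction uses the multivariate hypergeometric sampler, so zeros stay
  zero and a sample already at depth is returned unchanged; samples below
  depth are dropped and reported.
* The prevalence boundary is strict ("more than 20 %"); a flag relaxes it.
* The abundance filter reads both thresholds as dataset totals — the
  per-sample reading would remove nearly everything at depth 10,000.
* Lasso fits use coordinate descent with max_iter 5000; exact zeros in the
  coefficient vector define edge support (no epsilon thresholding).
* All-equal DNA concentrations make the contaminant score undefined
  (warned, unscored); an all-zero ANOVA decomposition returns F = 0 rather
  than 0/0.
* Every stochastic routine takes an explicit seed; the pipeline expands one
  global seed into per-stage seeds by hashing the stage name, so stages are
  independently reproducible.

## Problem sizes used by the test suite and acceptance script

Network recovery runs 5 seeds at p = 60, n = 150 (≈ 10 s per seed);
modularity is checked against exhaustive partition enumeration on 200
random graphs of 4–8 nodes; PERMANOVA calibration uses 500 null replicates
(3 × 10 samples, 199 permutations each) plus full enumeration of a
6-sample toy; power checks use 25 replicates at n = 30 (balanced groups)
and 50 dispersion replicates at n = 40. These sizes keep the whole suite
within a few minutes on a single CPU while leaving each statistical check
well-powered.

## Known limitations

* The contaminant score is a fixed-slope approximation isolated behind
  `frequency_score`; swapping in another scorer does not touch the
  threshold-sweep rule.
* Precision of network recovery at n = 150 is bounded near 0.6–0.7 by the
  irrepresentable-condition and clr-closure mechanisms described above.
* The dispersion test's handling of negative-eigenvalue axes subtracts
  squared imaginary contributions with a floor at zero — the standard
  real-axes approximation, exact only for Euclidean-embeddable
  dissimilarities.
* Module detection ignores edge weights; a `--weights abs` style option
  can be emulated by passing a weighted graph directly to networkx, but
  signed-weight modularity is deliberately out of scope.
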