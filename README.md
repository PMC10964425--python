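# gutweb

Multi-kingdom gut-microbiome co-occurrence analysis for amplicon count
tables, built around the statistical workflow used to study how the
filamentous gut fungus *Basidiobolus* is co-structured with bacterial
communities in herptile (frog, lizard, salamander) hosts.

The package is aimed at microbial ecologists who have 16S + ITS amplicon
count tables (features × samples), sample metadata (host, geography, DNA
concentration, no-template controls) and, optionally, a phylogenetic tree —
and who want a tested, reproducible route from raw counts to co-occurrence
networks, keystone taxa, indicator statistics and community-level tests.

## What it computes

1. **Contaminant screening** (`gutweb.decontamination`). Reagent
   contaminants arrive at a fixed number of molecules per library, so their
   relative abundance varies inversely with template DNA concentration.
   Each feature is scored by comparing a log-frequency ~ log-concentration
   model with slope fixed at −1 against a flat model (an F-type tail
   probability; low score = contaminant-like). The flagging threshold is
   chosen by sweeping the grid t ∈ {0.05, 0.15, …, 0.95} and selecting the
   last value at which the *marginal* removal still takes more sequence
   from no-template-control (NTC) libraries than from real samples, given
   at least 10 % of NTC sequences are removed.

2. **Preprocessing** (`gutweb.preprocessing`). Rarefaction without
   replacement to a common depth (multivariate hypergeometric), a > 20 %
   prevalence filter, a dataset-total abundance filter (≥ 10 reads and
   ≥ 0.5 % relative abundance), and top-N-by-abundance selection.

3. **Network inference** (`gutweb.network_inference`). The latent Gaussian
   graphical-model route for compositional counts: centered log-ratio (clr)
   transform, per-node L1-penalized neighborhood regressions
   (Meinshausen–Bühlmann, OR symmetrization, signed weights), and StARS
   stability selection — the densest penalty whose edge set keeps total
   instability D(λ) = mean 2θ(1−θ) at or below β = 0.05 across 20
   subsamples of size ⌊10√n⌋ (capped at 0.8 n).

4. **Topology and keystones** (`gutweb.network_topology`). Edge density,
   transitivity, fast-greedy (Clauset–Newman–Moore) modules with Newman
   modularity Q = Σ_c (e_cc − a_c²), top-30 %-degree hub subnetworks, and
   keystone classification in the (Zi, Pi) plane: within-module degree
   z-score versus among-module participation coefficient, with the usual
   thresholds Zi = 2.5 and Pi = 0.62 separating peripherals, connectors,
   module hubs and network hubs.

5. **Indicator power** (`gutweb.indicator_power`). For presence/absence
   vectors, IP = √(a·b) with a = P(target | indicator) and
   b = P(no target | no indicator); mean IP per bacterial class, total
   indicator power (TIP) per fungal target, and the Pearson /
   complete-linkage heatmap ordering.

6. **Community ecology** (`gutweb.community_ecology`). Bray-Curtis
   dissimilarity, PCoA, a betadisper-style test of multivariate dispersion
   homogeneity (spatial-median centers, negative-eigenvalue correction),
   PERMANOVA with crossed factors and interaction (sequential sums of
   squares, free permutation of sample labels, add-one p estimator), and
   patristic distance matrices from newick trees.

7. **Synthetic data with known truth** (`gutweb.synthetic_data`). A
   Gaussian-copula (normal-to-anything) generator with zero-inflated
   negative-binomial margins whose dependence comes from a planted sparse
   interaction graph; planted contaminants with the inverse-concentration
   signature plus NTC libraries; planted multiplicative host-group effects;
   and random binary trees. Every downstream stage therefore has a
   recoverable target.

## Worked example

```python
from gutweb import (make_truth, simulate_counts, clr_transform,
                    stars_select, global_stats)

truth = make_truth(p=60, topology="modular", n_modules=6, density=0.05,
                   seed=1, group_effect_multiplier=1.0)
table, meta = simulate_counts(truth, n_samples=150)
net = stars_select(clr_transform(table), beta_target=0.05,
                   n_subsamples=20, seed=1)

true_edges, est = truth.edge_id_set(), net.edge_id_set()
tp = len(est & true_edges)
print(f"planted edges: {len(true_edges)}   estimated: {len(est)}")
print(f"precision: {tp/len(est):.3f}   recall: {tp/len(true_edges):.3f}")
print(global_stats(net))
```

prints

```
planted edges: 88   estimated: 113
precision: 0.496   recall: 0.636
{'n_nodes': 60, 'n_edges': 113, 'edge_density': 0.0638,
 'transitivity': 0.2064, 'n_modules': 9, 'modularity': 0.5560,
 'pct_negative_edges': 40.7}
```

Here 88 pairwise interactions were planted in a 6-module graph; at n = 150
samples the stability-selected network recovers 64 % of them, at the cost
of some extra within-module and closure-induced edges (precision varies
roughly 0.50–0.70 across seeds; it rises above 0.84 by n = 300 — see
`docs/methods.md` for why n = 150 sits below the precision phase
transition for this graph). The module structure (Q = 0.556) and the mostly
sparse topology (edge density 0.064) are the quantities the topology stage
summarizes for real data.

A shell-level pipeline is available through the `gutweb` command
(`simulate`, `decontam`, `preprocess`, `network`, `indicator`, `ecology`,
`patristic`, `run`), each writing tab-separated outputs plus a JSON run
manifest with config hashes and file digests.

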