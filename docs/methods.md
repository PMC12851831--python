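# Methods

This document describes the statistical models behind each `proteoscale`
stage, the default parameters and their rationale, the scope of the
synthetic data generator, and known limitations. Empirical performance
numbers quoted here are the ones computed by `scripts/acceptance.py` and the
test suite; nothing else is claimed.

## Synthetic cohort generator (`synthdata`)

`generate_cohort(CohortConfig)` draws a feature × donor abundance matrix
with known ground truth (`SyntheticTruth`):

- **Features.** `n_genes` genes; a random subset carries a second isoform
  (`GENE.2`) sharing a fraction `isoform_shared_var = 0.5` of its variance
  with the first, so isoform→gene collapsing has real work to do.
- **Modules.** `n_modules` disjoint blocks of sizes `module_sizes` follow a
  one-factor Gaussian model: feature *j* in module *k* is
  `sqrt(r)·f_k + sqrt(1 − r)·ε`, giving pairwise correlation exactly
  `r = within_module_cor` in expectation
  (`within_module_cor = 0.6` by default).
- **Traits.** A latent severity score per donor is discretized into Braak,
  CDR, CERAD, plaque and MMSE columns with realistic codings; CDR and CERAD
  share correlation `cdr_cerad_cor = 0.6` so consensus signatures overlap
  without being identical.
- **Differential abundance.** A fraction `de_frac = 0.15` of features gets a
  linear severity effect of size `de_effect = 0.8` (in residual-SD units)
  with recorded sign.
- **Causal blocks.** `n_snps` biallelic variants (MAF `snp_maf = 0.3`) each
  drive one source feature with slope `eqtl_beta = 1.0`; each of `n_drivers`
  driver features propagates through a fan-out tree of
  `n_descendants_per_driver` features to depth `causal_depth = 2`, each edge
  adding `causal_beta`-scaled signal plus `causal_noise_sd = 0.7` noise.
  Causal features never overlap modules or planted DE features, so each
  stage's ground truth is unambiguous.
- **Pseudobulk.** `generate_pseudobulk_counts` draws negative-binomial
  single-cell counts (dispersion `nb_dispersion = 0.5`) for
  `n_donors × cell types × cells_per_donor_type` cells; `n_coupled_pairs`
  cross-cell-type gene pairs share a donor-level latent factor with strength
  `coupling_strength`.
- **Scope.** The generator is Gaussian/negative-binomial, blockwise
  independent, and free of batch structure, confounding between traits and
  genotype, or missing-not-at-random patterns. It is designed to make every
  stage's target quantity recoverable and scorable, not to mimic any real
  cohort's marginal distributions.

## Preprocessing (`preprocess`)

- `filter_missing(max_missing_frac = 0.5)` drops features whose missing
  fraction *strictly exceeds* the threshold (a feature missing in exactly
  half the samples survives the default).
- `impute_missing(k = 10)` is k-nearest-feature imputation: Euclidean
  distance on co-observed samples, inverse-distance-weighted mean over
  neighbors observed at that sample. Observed entries are never modified;
  an all-missing feature is an error, not a silent zero.
- `adjust_covariates` returns per-feature OLS residuals; categorical
  covariates expand to indicators (first level dropped) and aliased design
  columns are removed with a warning. Residuals are orthogonal to every
  retained covariate column to numerical precision (pseudoinverse-based hat
  matrix).
- `tmm_factors(trim_m = 0.30, trim_a = 0.05)` implements trimmed mean of
  M-values with delta-method precision weights. Because the weights depend
  on raw counts, factors are only *approximately* invariant to pure depth
  rescaling (the test suite allows 0.02 absolute deviation).

## Differential abundance (`diffexpr`)

The moderated t-test shrinks each feature's variance `s²` (on `d` residual
degrees of freedom) toward a prior `s₀²` with prior degrees of freedom `d₀`:

```
s̃² = (d0·s0² + d·s²) / (d0 + d),   t = Δ / (s̃·c),   df = d + d0
```

`fit_moderation` estimates `(d₀, s₀²)` by moment matching on `log s²`: the
excess variance of `log s²` over the theoretical `trigamma(d/2)` determines
`d₀` via a Newton inversion of trigamma, and `s₀²` carries the chi-square
log-bias correction `s₀² = exp(mean(log s²) − digamma(d/2) + log(d/2))`.
Two exact limits anchor the implementation: `d₀ = 0` reproduces the pooled
two-sample t-test to 1e-10, and constant observed variances drive `d₀ → ∞`
with `s₀²` equal to the closed form above.

- `benjamini_hochberg` is the standard step-up procedure (cross-checked
  against `statsmodels` and the hand example {0.01, 0.02, 0.03} →
  {0.03, 0.03, 0.03}).
- `stratify_samples` encodes three-level trait boundaries (Braak Low ≤ 2 <
  Medium ≤ 4 < High; CDR Nondemented = 0 / Impaired ≤ 2 / Demented > 2;
  plaque Normal = 0 / Mild ≤ 9 / Severe; MMSE tertiles; CERAD with
  cohort-specific codings in which the "definite" code is 2 for one coding
  and 1 for the other).
- `call_deps(fc_thresh = 1.1, fdr_thresh = 0.05)` applies a fold-change and
  FDR gate; presets bundle cohort-specific defaults.
- `consensus_signature` requires majority agreement in direction across
  trait contrasts and is order-invariant; `sex_stratified_stability`
  down-samples (`n_iter = 1000`, selection frequency ≥ 0.8) and a full-size
  resample equals a single call exactly.
- `trait_correlation` computes Spearman correlation as Pearson on ranks and
  flags degenerate (constant) inputs instead of returning NaN silently.

Under a global null (no planted effects), the empirical false discovery
proportion of the full stratify → moderate → BH → call chain averages below
the nominal 0.05 level over seeds (acceptance criterion; the observed value
is reported by `scripts/acceptance.py`).

## Co-expression network (`coexnet`)

- `significant_pairs(fdr = 0.05, min_abs_rho = 0.0)` computes all pairwise
  correlations in one BLAS pass, tests them with the exact t transform, and
  BH-controls the family. `min_abs_rho` is an optional effect-size gate:
  with p features there are O(p²) null pairs, so a small count of pure-noise
  pairs always survives FDR control, and a single spurious edge can bridge
  two otherwise separate modules. A floor near the upper tail of the null
  correlation distribution — about `4/√n_samples`, i.e. four null standard
  errors — removes these without touching genuine module edges (planted
  within-module correlation 0.6 ≫ 4/√185 ≈ 0.29 at the default cohort
  size). The floor is derived from the null sampling distribution, not
  tuned to any dataset.
- `build_pfn` inserts candidate edges in descending |ρ| and keeps each edge
  only if the graph stays planar (`networkx.check_planarity`), the planar
  maximally filtered network. Every output satisfies |E| ≤ 3|V| − 6; the
  complete graph K5 retains exactly 9 of its 10 edges. A combinatorial
  planarity test is equivalent to spherical embeddability, so no geometric
  embedding is needed.
- `multiscale_cluster(min_size = 10, n_null = 100, alpha = 0.05)` builds a
  rooted module hierarchy top-down. Disconnected candidates split into
  connected components. A connected module is split by weighted-modularity
  (Louvain, weight = |ρ|) and the split is accepted only when the gain in
  *compactness* (mean within-part inverse shortest-path length) exceeds the
  (1 − alpha) quantile of gains obtained on degree-preserving rewires
  (`double_edge_swap`) of the module subgraph. This null is deliberately
  conservative: on small dense graphs (e.g. two cliques joined by one
  bridge) rewires retain enough clustering that real two-way splits can be
  rejected; structure spanning several communities is detected reliably.
  The planted-module recovery acceptance run scores the hierarchy at
  scale 1 (modules directly under the root), the resolution that matches
  flat planted structure — deeper scales legitimately refine further.
- `detect_hubs(n_perm = 1000, alpha = 0.05)` compares each node's degree to
  the maximum degree of G(n, m) random graphs with the module's node and
  edge counts, with add-one p-value correction. Modules smaller than 3
  return an empty table.

## Module characterization (`modulechar`)

- `hypergeometric_enrichment` is the right-tail hypergeometric test with
  fold enrichment FE = (k/m)/(K/N); for N ≤ 20 it matches brute-force
  enumeration over all `C(N, m)` module draws exactly. One BH family per
  `adjust_enrichments` call.
- `rank_modules` scores each module by Σ −log₁₀(adjusted p) over its
  records, flooring p at 1e-300 to keep scores finite; ties break by module
  id.
- `zsummary_preservation(n_perm = 200)` permutes module membership in the
  reference matrix and summarizes density (mean |ρ|) and connectivity
  (correlation of intra-module connectivity between source and reference)
  as Z-scores; Zsummary = mean of the two, with > 6 called preserved.
  The connectivity component is only informative when the module has hub
  structure (heterogeneous correlations); for a perfectly homogeneous
  module it is noise, which is why both the tests and the generator use
  heterogeneous factor loadings when exercising it.
- `gsea(weight = 1.0)` is the weighted Kolmogorov–Smirnov running-sum
  statistic with sign-aware permutation p-values; `weight = 0` reduces to
  the classic KS form, which the tests verify against a direct
  implementation.

## Causal networks (`causalnet`)

- `compute_eqtls(fdr = 0.05, min_minor_allele_count = 5)` regresses each
  feature on allele dosage (matches `scipy.stats.linregress` to 1e-10) and
  BH-controls across all (SNP, feature) pairs; monomorphic or rare variants
  are skipped.
- `cit_test` evaluates the causal chain L → A → B through four component
  tests: (1) L associated with B, (2) L associated with A given B,
  (3) B associated with A given L, and (4) L independent of B given A.
  Component 4 is an equivalence-style test using a noncentral-F surrogate
  for the residual association, so "independence" is demonstrated rather
  than assumed from a failed rejection. Both orientations are evaluated and
  a direction is returned only when exactly one orientation passes all four
  components; otherwise the pair is undecided. At n = 300, slope 1.0 and
  noise SD 0.5, direction accuracy exceeds 90% over 100 replicates
  (acceptance criterion).
- `assemble_priors` turns decided CIT orientations into hard forbidden
  reverse edges and TF–target pairs into soft score bonuses; conflicting
  hard constraints are dropped with a warning.
- `mcmc_structure_search(edge_penalty = 2.0, max_parents = 3)` runs
  Metropolis–Hastings over DAGs scored by Gaussian BIC per node plus prior
  bonuses minus a per-edge sparsity penalty. The penalty of 2.0 (on the
  log-score scale, on top of BIC's own complexity term) keeps null-data
  networks sparse: under pure noise the expected consensus edge count stays
  well below 5% of candidate edges. Node scores are memoized in a cache
  shared across ensemble chains.
- `sample_ensemble(n_networks = 100)` runs independent chains with
  per-chain derived seeds; `consensus_network(freq_thresh = 0.3)` keeps
  edges supported by *strictly more* than 30% of chains; `deloop` removes
  the weakest-supported edge inside any nontrivial strongly connected
  component (frequency ties break lexicographically) until the graph is
  acyclic.
- `key_driver_analysis(h = 2, min_neighborhood = 10)` tests each node's
  ≤ h-step downstream neighborhood for hypergeometric enrichment of a
  signature, BH-adjusts, and ranks. Sink nodes and nodes with small
  neighborhoods are excluded. On cohorts with one planted driver and a
  depth-2 fan-out, the driver ranks in the top 5 in ≥ 90% of seeds
  (acceptance criterion).

## Cross-cell-type analysis (`crosscell`)

- `pseudobulk_aggregate` sums counts per (donor, cell type); totals are
  conserved and absent combinations are logged, not invented.
- `normalize_pseudobulk` applies TMM factors and log₂ CPM, indexing rows as
  `gene@celltype` composite features over donor columns.
- `cross_celltype_correlations(rho_thresh = 0.2, fdr_thresh = 0.05,
  min_donors = 10)` tests every unordered pair of composite features from
  *different* cell types (same-cell-type pairs are never tested) and calls
  a pair significant only if it passes both the FDR and the |ρ| gate. Under
  a null with no planted couplings the significant-call count stays at the
  BH-expected level (acceptance criterion).

## Determinism and seeding

Every stochastic stage takes an explicit seed. Derived seeds use
`np.random.default_rng([master_seed, stage_counter, k]).integers(2**31 − 1)`
— the SeedSequence spawn of a list key — so stages are decoupled (changing
the replicate count of one stage does not shift another's stream) and all
derived seeds stay below 2³¹. Reruns with the same config and master seed
are byte-identical, including MCMC ensembles, permutation tests and the
generator (verified per stage by the determinism acceptance test).

## Limitations

- The compactness-null split test is conservative on small dense graphs;
  two-community structure joined by a single bridge may not be split even
  when visually obvious. Missed splits are the expected failure mode, not
  spurious ones; raise `alpha` to trade specificity for sensitivity.
- TMM factors are only approximately depth-invariant (precision weights).
- The CIT component-4 surrogate controls the equivalence test's size only
  approximately; extremely strong confounding can still yield undecided
  rather than wrong calls, which is the intended failure mode.
- `mcmc_structure_search` caps problem size at `max_features = 300`;
  consensus + deloop guarantees acyclicity but not identifiability beyond
  the Markov equivalence class except where genetic anchors break ties.
- The generator does not model batch effects, missing-not-at-random
  dropout, trait–genotype confounding, or heavy-tailed abundance noise;
  conclusions about robustness to those must come from elsewhere.
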