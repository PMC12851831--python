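# proteoscale

Multiscale proteomic co-expression and causal network analysis for
case–control brain cohorts.

## The problem

Deep proteomic profiling of postmortem brain cohorts (a few hundred donors,
~10⁴ protein isoforms, graded neuropathological and cognitive traits) raises
a chain of analysis questions that no single tool answers end to end:

1. Which proteins change with disease severity, once technical and
   demographic covariates are removed and the per-feature variance estimates
   are stabilized across thousands of features?
2. How is the proteome organized into co-expression modules, at more than
   one resolution, and which modules track disease, map to cell types, and
   reproduce in independent cohorts or other omics layers?
3. Within disease-relevant subnetworks, which proteins are *causal drivers*
   rather than passengers — using genetic variation as an anchor for
   direction — and which proteins in one cell type co-vary with proteins in
   another?

`proteoscale` implements this pipeline as a library plus CLI:

- **preprocess** — missingness filtering, k-nearest-feature imputation,
  covariate residualization, TMM scale factors for count data.
- **diffexpr** — three-level trait stratification (Braak, CDR, CERAD,
  plaque density, MMSE), an empirical-Bayes moderated t-test
  (per-feature variance s² shrunk toward a prior s₀² with prior degrees of
  freedom d₀ fit by moment matching on log s²), Benjamini–Hochberg FDR,
  per-cohort calling presets, cross-trait consensus signatures,
  down-sampling stability selection, and protein-vs-transcript concordance.
- **coexnet** — a planar maximally filtered co-expression network (greedy
  edge insertion in descending |ρ| subject to planarity, so |E| ≤ 3|V| − 6),
  recursive multiscale module detection (a split is kept only when its
  compactness gain beats degree-preserving rewires), and degree-based hub
  detection against a random-graph null.
- **modulechar** — hypergeometric signature enrichment with fold enrichment
  (k/m)/(K/N), module disease-ranking by Σ −log₁₀ FDR, permutation
  Zsummary preservation (> 6 = preserved), conservation/specificity calls,
  and weighted-KS gene-set enrichment analysis.
- **causalnet** — cis-eQTL detection, the causal inference test (CIT) to
  orient feature pairs sharing a variant, Metropolis–Hastings search over
  Gaussian-BIC-scored DAGs with structural priors, ensemble consensus
  (> 30% edge frequency), cycle removal, and key driver analysis
  (hypergeometric enrichment of h-step downstream neighborhoods).
- **crosscell** — donor-level pseudobulk (sum per donor × cell type), TMM +
  log₂ CPM, and cross-cell-type correlation calling.
- **synthdata** — a seeded generator of synthetic cohorts with planted
  modules, differential abundance, eQTL-driven causal fan-outs, and
  cross-cell-type couplings, so every stage can be scored against known
  ground truth.

## Worked example

```python
import numpy as np
from proteoscale.synthdata import CohortConfig, generate_cohort
from proteoscale import diffexpr, coexnet

# trait-stratified differential abundance on a default synthetic cohort
cfg = CohortConfig(seed=7)
expr, meta, geno, truth = generate_cohort(cfg)
print(f"cohort: {expr.shape[0]} features x {expr.shape[1]} donors")

groups = diffexpr.stratify_samples(meta, "CDR")
hi, lo = groups.extreme_contrast
res, params = diffexpr.moderated_ttest(expr, groups.samples(hi), groups.samples(lo))
up, down = diffexpr.call_deps(res, preset="msbb-protein")
print(f"{hi} vs {lo}: {len(up)} up, {len(down)} down (prior df d0 = {params.d0:.1f})")
planted = set(truth.de_direction["CDR"])
print(f"calls overlapping planted DE features: {len((up | down) & planted)} of {len(up | down)}")

# planar network and multiscale modules on a module-structured cohort
mcfg = CohortConfig(seed=7, n_genes=80, n_modules=3, module_sizes=(20, 20, 20),
                    de_frac=0.0, de_effect=0.0, covariate_effects={},
                    n_drivers=0, n_descendants_per_driver=0)
mexpr, _, _, mtruth = generate_cohort(mcfg)
pairs = coexnet.significant_pairs(mexpr, fdr=0.05, min_abs_rho=4 / np.sqrt(185))
pfn = coexnet.build_pfn(pairs)
hier = coexnet.multiscale_cluster(pfn, min_size=10, n_null=20, seed=0)
print(f"planar network: {len(pfn.nodes)} nodes, {pfn.n_edges} edges, planar = {pfn.is_planar()}")
top = [m for m in hier.modules if hier.scale[m] == 1]
print(f"top-level modules: {len(top)} with sizes {sorted(len(hier.modules[m]) for m in top)}")
```

Output:

```text
cohort: 254 features x 185 donors
Demented vs Nondemented: 17 up, 23 down (prior df d0 = 429.5)
calls overlapping planted DE features: 38 of 40
planar network: 78 nodes, 174 edges, planar = True
top-level modules: 3 with sizes [20, 20, 20]
```

The three planted 20-feature modules are recovered exactly.

## CLI

```bash
proteoscale simulate --out-dir fixture --n-genes 120 --seed 2
proteoscale run --config config.yaml     # full pipeline from YAML/JSON
proteoscale dep --expression fixture/expression.tsv \
    --metadata fixture/metadata.tsv --trait Braak --out dep.tsv
```

Subcommands: `simulate`, `preprocess`, `dep`, `network`, `modules`,
`conserve`, `causal`, `kda`, `crosscell`, `gsea`, `run`. All stages take a
single master seed; per-iteration and per-chain seeds are derived from it by
counter, and a rerun with the same config and seed reproduces byte-identical
outputs.

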