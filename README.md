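# coexatlas

Gene co-expression network analysis for expression atlases: variance
filtering, hard-threshold (density-calibrated) networks, sample-redundancy
weighted correlation with Mutual Rank, WGCNA-style soft thresholding with
topological overlap, Markov Clustering tuned by term enrichment, and
physiochemical characterization of protein sequences.

## Who this is for

Plant systems biologists (and anyone with a genes × samples compendium of
normalized expression values) who want to place a gene family in its
co-expression context: which genes travel together across hundreds of
arrays, which modules they form, and what those modules are enriched for.
The package reimplements, as a tested and reusable library, the network
methodology commonly applied to microarray atlases such as the *Medicago
truncatula* Gene Expression Atlas, together with a synthetic-atlas
generator so the full pipeline can be validated against planted ground
truth without any downloads.

## The methods in brief

- **Gene filters.** A gene enters the network when sd/mean ≥ 0.5 and
  max − min > 32 over all samples (raw scale); surviving values are
  log₁₀-transformed with negative transforms clamped to 0.
- **Unweighted network.** Pearson correlation r for all gene pairs; an edge
  joins pairs with r ≥ t. The cutoff t is calibrated by scanning a grid and
  minimizing the network density E / (N(N−1)/2) over the surviving
  (degree ≥ 1) nodes. Topology statistics: clustering coefficient
  C\_n = 2e\_n / (k\_n(k\_n−1)), connected components, characteristic path
  length, log–log degree-frequency fit.
- **Markov Clustering (MCL).** Flow simulation on the column-stochastic
  graph matrix, alternating expansion (matrix squaring) and inflation
  (elementwise power r with renormalization). The inflation parameter is
  swept over 1–5 in steps of 0.1 and scored by hypergeometric term
  enrichment of the resulting clusters against the whole-network background
  (BH-corrected, FDR < 0.05); the inflation with the most enriched clusters
  wins.
- **Sample-weighted correlation and Mutual Rank.** Sample similarity
  J = corr(sample a, sample x) is thresholded at C = 0.4 and rescaled,
  J′ = (J − C)/(1 − C); a sample's redundancy is its J′ row sum and its
  weight W = redundancy^(−1/2). The weighted Pearson correlation uses these
  weights, and MR(A,B) = √(Rank\_{A→B} · Rank\_{B→A}) converts correlations
  to mutual ranks (network edge when MR ≤ 100).
- **Soft threshold / WGCNA-style modules.** Adjacency a\_ij = |r\_ij|^β with
  β the smallest power whose connectivity distribution is scale-free
  (signed R² ≥ 0.8); topological overlap
  TOM\_ij = (l\_ij + a\_ij)/(min(k\_i,k\_j) + 1 − a\_ij); average-linkage
  tree cut into modules; module eigengenes (first principal component) and
  per-gene module membership.
- **Protein properties.** Average molecular weight, Bjellqvist-convention
  isoelectric point (charge-balance bisection), Guruprasad instability
  index, residue composition percentages.

## Worked example

Generate the default synthetic atlas (200 genes: 4 planted modules of 30,
40 weakly-paired background genes, 40 near-constant genes; 100 samples
including 3 blocks of 8 near-duplicate arrays) and run the full pipeline:

```python
from coexatlas import AtlasSpec
from coexatlas.pipeline import run_synthetic

manifest = run_synthetic(AtlasSpec(seed=1))
stages = manifest["stages"]
print("genes kept:", stages["filter"]["n_kept"], "of", stages["filter"]["n_input_genes"])
print("selected PCC cutoff:", stages["cutoff_scan"]["selected_cutoff"])
print("network:", stages["network"]["n_nodes"], "nodes,",
      stages["network"]["n_edges"], "edges")
print("optimal inflation:", stages["mcl_sweep"]["optimal_inflation"])
print("module recovery ARI:", manifest["recovery"]["adjusted_rand_index"])
print("planted terms significant:", manifest["recovery"]["planted_terms_significant"])
```

prints

```
genes kept: 160 of 200
selected PCC cutoff: 0.36
network: 160 nodes, 1788 edges
optimal inflation: 1.0
module recovery ARI: 1.0
planted terms significant: ['T001', 'T002', 'T003', 'T004']
```

The variance filters removed exactly the 40 near-constant genes; the
density scan picked a cutoff at which all four planted modules survive as
intact near-cliques while the background contributes only weakly-connected
pairs; the enrichment-scored inflation sweep then recovered the planted
modules perfectly (adjusted Rand index 1.0) and flagged each module's
planted annotation term at FDR < 0.05.

The same stages are available from the shell:

```sh
coexatlas simulate --out sim/ --seed 1
coexatlas filter --atlas sim/atlas.tsv --out filtered.tsv
coexatlas correlate --atlas filtered.tsv --method pcc --out corr.tsv
coexatlas net density-scan --corr corr.tsv --out scan.tsv
coexatlas protprops --fasta sim/proteins.fasta --out props.tsv
```

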