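# Methods

This note documents the models implemented in `coexatlas`, the parameter
conventions and defaults, the design of the synthetic data used to validate
the pipeline, and the numerical choices a maintainer would want recorded.

## Gene filtering and transformation

Genes enter the analysis when (1) the coefficient of variation of their raw
expression, sample sd / mean, is ≥ `cv_min` (default 0.5) and (2) their
expression range max − min is strictly greater than `range_min` (default
32 raw units). The sd is the sample (n−1) formula — expression tooling
convention; a population-sd variant would change the CV by < 1% at atlas
sample sizes. Rows with zero mean fail the CV criterion rather than raising.
Surviving values are transformed as max(0, log₁₀ v): raw values below 1
(including 0) clamp to 0. Both filters are idempotent.

## Unweighted network and cutoff calibration

Pearson correlation is computed on the log₁₀ values for all gene pairs
(constant rows get a correlation of 0 with a logged warning). A cutoff t
turns the correlation matrix into an undirected graph over the genes with
at least one passing edge. When probe-level rows carry a probe → gene map,
edges between two probes of one gene model are discarded.

Network density is E / (N(N−1)/2) with N the surviving (degree ≥ 1) node
count. This convention is locked in by the published full-network counts —
68,428 edges over 4,257 nodes give 0.00755 ≈ 0.0075, and the root network's
42,855 / 2,663 give 0.0121 — which only hold with the surviving-node
denominator. An all-genes denominator is available behind a flag. The
cutoff is chosen to minimize density over a grid (default 0 to 1, step
0.01; ties go to the smallest cutoff), which maximizes the separation of
correlated blocks from the background and hence the clustering potential.
Cutoffs leaving fewer than two connected nodes yield null records that the
selector skips.

Topology statistics: per-node clustering coefficient
C_n = 2e_n/(k_n(k_n−1)) with C_n = 0 for degree < 2 (the formula is 0/0
there; a mean restricted to degree ≥ 2 nodes is available); components
sorted by size; characteristic path length averaged over ordered reachable
pairs only (multi-component graphs contribute no infinite paths); degree
power-law fit as least squares of log₁₀ frequency on log₁₀ degree with
zero-frequency bins removed, requiring ≥ 3 distinct degrees.

## Markov Clustering and the inflation sweep

MCL runs on the adjacency plus unit self-loops, column-normalized.
Each iteration squares the matrix (expansion), raises it elementwise to the
inflation power and renormalizes (inflation), and zeroes entries below
`prune_eps` (1e-6). Convergence is a maximum column change below `conv_tol`
(1e-8), capped at `max_iter` (200) with a warning and best-iterate clusters
on non-convergence. Attractors are rows with diagonal flow above 1e-6;
attractor systems sharing flow merge; every node joins the system giving it
the largest flow, ties resolved toward the system containing the smallest
attractor index, so the clustering is invariant to node relabeling.
Inflation 1 is accepted but degenerate: the iteration reduces to pure
expansion and each connected component converges to a single cluster.

The inflation grid (default 1–5, step 0.1) is scored by hypergeometric
enrichment of each clustering against the whole-network background: the
optimal inflation yields the most clusters with at least one term at
FDR < 0.05, ties broken by the most enriched terms per enriched cluster,
then by the smallest inflation. Clusters below `min_cluster_size` (default
5) are not tested.

## Sample-redundancy weights, weighted PCC, Mutual Rank

Expression compendia contain blocks of near-duplicate arrays. Sample
similarity J is the Pearson correlation between sample columns; values
below C = 0.4 are set to 0 and the rest rescaled to J′ = (J − C)/(1 − C).
A sample's redundancy is its J′ row sum *including* the self term
(J′aa = 1), so redundancy ≥ 1 and the weight W = redundancy^(−1/2) obeys
0 < W ≤ 1; negative similarities simply fall below C. The weighted PCC uses
weighted means and weighted covariance/variance sums; uniform weights
reproduce the plain PCC to machine precision and a zero-weight sample is
equivalent to deleting it.

Mutual Rank: each gene ranks all partners 1..n−1 by descending weighted
correlation (ties get fractional/average ranks — deterministic and
symmetric); MR(A,B) = √(Rank_{A→B} · Rank_{B→A}). The square root follows
the "geometric average" definition; the bare rank product is available via
`geometric=False`. MR is symmetric, bounded in [1, n−1], and invariant
under any rank-preserving transform of the correlations. The MR network
keeps pairs with MR ≤ 100 by default; the disconnected-node fraction curve
(grid 5–200, step 5) is computed over all genes in the matrix.

## Soft-threshold network

Unsigned adjacency a_ij = |r_ij|^β, diagonal excluded from connectivity.
β is the smallest candidate whose binned connectivity distribution fits a
power law: 10 equal-width connectivity bins, least squares of log₁₀
frequency on log₁₀ mean-connectivity, signed R² = −sign(slope)·R², pass at
R² ≥ 0.8 (the customary scale-free-fit convention; degenerate all-equal
connectivities record a null fit). TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) +
1 − a_ij) with l_ij = Σ_u a_iu a_uj. Modules come from average-linkage
hierarchical clustering of 1 − TOM cut at a static height (default 0.99 of
the tallest merge, minimum module size 30): a deterministic, testable
stand-in for the dynamic branch cut, preserving the branch-cut concept.
Module eigengenes are the first principal component of the module's
per-gene standardized expression, sign-oriented to correlate non-negatively
with the module mean profile; membership is the correlation of any gene
with an eigengene.

## Enrichment

One-sided (over-representation) hypergeometric upper tail per
(cluster, term) pair with k ≥ 1, tested against a caller-supplied
background; Benjamini–Hochberg correction across all pairs of one
invocation (the conservative default for sweep scoring; a per-cluster
family is a caller-side restriction of the annotation). Significance is
q < 0.05 by default.

## Protein physiochemistry

Average (not monoisotopic) amino-acid masses with one water (18.0153 Da)
per chain; isoelectric point by bisection of the Henderson–Hasselbalch net
charge over D, E, C, Y, H, K, R and the termini, with the Bjellqvist pKa
set including residue-specific terminal values, to |charge| < 1e-4 on
pH ∈ [0, 14] (the charge is strictly decreasing in pH, so bisection always
converges); instability index (10/L)·Σ DIWV(x_i, x_{i+1}) over the
published dipeptide weights; composition as 100·count/length. Ambiguity
codes (B, Z, X) are rejected, not approximated. All four agree with the
Biopython ProtParam implementation to well below reporting precision
(tested on 100 random sequences).

## Synthetic atlas: what it emulates, and what it does not

The generator produces a raw-scale genes × samples matrix with known
structure:

- **Planted modules.** Module genes are loading × (signal·latent + noise)
  on the log scale (loadings uniform in [0.7, 1.5]), exponentiated to raw
  scale. The signal/noise split pins every within-module gene pair at the
  module's target correlation. Module targets are *staggered* around
  `within_module_corr` (multipliers spread by `corr_stagger`, default 0.9,
  normalized to keep the family mean on target; for the default 0.95 the
  four modules sit near 0.905/0.935/0.965/0.995). The stagger reflects a
  real feature of expression compendia — modules differ widely in tightness
  — and it is what produces the interior minimum of the density curve: as
  the cutoff rises, whole modules drop out one at a time (raising density)
  instead of all modules eroding edge-by-edge simultaneously (which
  produces a sparse fragmented graph whose density undercuts every
  module-preserving configuration; a homogeneous-correlation design
  therefore mis-calibrates the cutoff by construction, at any sample
  size). Homogeneous within-module correlation also keeps each module
  clique-like, so MCL clusters it whole at moderate inflations and
  disperses it into singletons at extreme ones — it never leaves mid-sized
  fragments that would distort the enrichment-scored sweep.
- **Background genes** form weakly correlated pairs (r ≈ 0.55): they enter
  the threshold scan far below the module correlations and pin the density
  minimum at a module-preserving cutoff, then appear in the network only as
  isolated two-gene components.
- **Flat genes** are a constant raw baseline plus clipped additive noise
  (CV ≈ 0.02, range < 16), safely inside both filter exclusions, so the
  variance filters remove exactly these genes.
- **Redundant samples**: trailing columns are copies of a block seed plus
  log-scale perturbation (default three blocks of 8 at sd 0.05), and the
  recorded module latents are updated to the duplicated state. Per-gene
  baseline offsets (log₁₀ ± 0.5) keep sample columns from being collinear.
- **Annotations**: one planted term per module covering `enrichment_frac`
  of its genes (plus optional background scatter), and random filler terms.
- **Proteins**: uniform random sequences over the 20 standard residues.

Defaults (200 genes, 4 × 30 module genes, 40 background, 40 flat,
100 samples, seed-deterministic throughout) were chosen once as a
desk-scale emulation of an atlas analysis and are exercised at seeds 1–5 by
the acceptance suite.

Not emulated: probe-level artifacts, normalization and batch effects (the
atlases this pipeline targets arrive normalized), heavy-tailed expression
distributions, correlated background beyond pairs, hierarchical annotation
(GO DAG structure), and real sample-condition structure. Passing the
recovery tests therefore demonstrates the *pipeline logic* — filters,
calibration, clustering, scoring — on data whose idealized correlation
structure is known; it does not certify performance on the messier
correlation landscapes of real compendia.

## Recovery scoring

Module recovery is the adjusted Rand index between recovered cluster labels
and planted module labels, computed over clustered genes that belong to a
planted module. Clustered background genes are counted separately as
contamination: the ground truth assigns all background genes one label, so
including them would penalize the *labeling convention* (20 correctly
isolated background pairs against one catch-all label cap the ARI near
0.79) rather than recovery quality.

## Known limitations

- The static-height tree cut is cruder than the dynamic hybrid cut; on
  strongly nested dendrograms it can merge adjacent modules at the default
  height.
- The scale-free fit uses 10 equal-width bins; very small networks
  (< ~50 genes) may yield too few occupied bins for a meaningful fit.
- MCL is dense-matrix; intended for networks up to a few thousand nodes,
  not the 20k+ probe scale (the inflation sweep multiplies that cost by
  the grid size).
- The MR "disconnected fraction" denominator is all genes in the MR matrix;
  an all-atlas-genes denominator would shift the curve by the filter ratio.
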