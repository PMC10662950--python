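# Methods

This note documents the models, conventions and parameter choices behind
`homoglia`, in the order the pipeline runs.

## The two-species count simulator

`simulate_two_species` draws a pair of UMI count matrices whose statistical
structure matches what the cross-species comparison machinery assumes:

- **Gene space.** `n_genes` genes per species, of which
  `round(n_genes * (1 - frac_nonortholog))` are shared orthologs under a
  common name; the remainder are private genes with species-specific names
  (default `frac_nonortholog = 0.10`). Private genes force the
  shared-feature-space logic downstream to be exercised rather than
  vacuously passed.
- **Cell types.** `n_types` shared types with an identity homology map.
  The last type is rare: instead of a full `cells_per_type_per_species`
  allotment it receives `rare_type_frac` of each dataset (default 5 %,
  ~53 cells next to five 200-cell types), standing in for a scarce
  progenitor subtype that label transfer must recover.
- **Expression model.** Each gene has a shared lognormal(0, 1) baseline.
  A cell of type *t* multiplies the type's marker block (disjoint blocks of
  `frac_marker_per_type` of the genes, drawn from the orthologs) by
  `exp(marker_log_effect)`; species B additionally multiplies a
  `species_shift_frac` fraction of orthologs by
  `exp(±species_shift_log_effect)` with random sign (defaults 0.10 and 0.5
  — a visible but not dominating species effect). The per-type relative
  expression vector is renormalized to sum to one, scaled by a lognormal
  library size (meanlog 8.5 ≈ 4900 UMIs, sdlog 0.3, truncated below at 100
  so no cell degenerates under the 200-detected-gene QC rule), and counts
  are drawn negative-binomial with `variance = mu + dispersion * mu^2`
  (default dispersion 0.1), the standard scRNA-seq noise model.
- **Reproducibility.** One `SeedSequence` is split in a fixed key order
  (shared structure, species A, species B), so outputs are byte-identical
  for a given seed and independent of generation order.

What the simulator does **not** emulate: developmental continua (types are
discrete), cell-cycle substructure, ambient RNA, doublets, batch effects
within a species, and realistic marker effect-size spectra (every marker of
a type carries the same log effect). Passing recovery tests therefore show
that the machinery is correct under its own assumptions, not that real
tissue will separate as cleanly; in particular the uniform effect makes
within-block genescore variation mostly sampling noise, so cross-species
genescore correlations on simulated data are low-r even when the argmax
structure is perfect.

## Preprocessing conventions

- QC keeps cells with detected-gene counts **strictly** between
  `min_genes = 200` and `max_genes = 5000` and a mitochondrial count
  fraction (computed on raw counts; genes flagged by the `MT-`/`mt-` name
  prefix unless explicit flags are supplied) strictly below 0.30. Genes
  must be detected in ≥ 3 cells; the gene filter runs before the cell
  filter, mirroring the usual two-pass construction (per-sample gene filter
  at object creation, cell filter on the merged object). Thresholds are
  per-run configuration, not constants — human datasets are often filtered
  at 6500 features / 5 % mitochondrial instead.
- Log-normalization: `ln(1 + 10000 * count / cell_total)` (natural log).
  The inverse identity `sum(expm1(row)) = 10000` is enforced by tests.
- HVG selection follows the variance-stabilizing (vst) scheme: per-gene raw
  count moments, a local linear regression (lowess, span 0.3) of
  log10(variance) on log10(mean), standardization by the fitted expected
  standard deviation, clipping at sqrt(n_cells), ranking by the clipped
  standardized variance. Where the lowess interpolator drops a point
  (duplicate or extreme abscissa) the fitted curve is linearly
  interpolated.
- Scaling is a per-gene population z-score clipped at ±10; zero-variance
  genes map to zeros. PCA is a dense SVD with a deterministic sign
  convention (largest-magnitude loading per component positive); variance
  shares are relative to the total variance of the scaled matrix, so they
  are non-increasing and sum to ≤ 1 by construction.

## Graph clustering

kNN sets (Euclidean in the leading 20 PCs, k = 20, the cell itself
included) are compared by Jaccard similarity; edges ≤ 1/15 are pruned.
Neighbor ties are broken by cell index via a stable argsort over the full
distance matrix — exact and reproducible at the cell counts this package
targets (tens of thousands), at O(n²) memory. Communities are found by
seeded Leiden on the RB-configuration quality function at resolution 0.8
by default; classic Louvain (igraph multilevel) is available behind
`method="louvain"`. Cluster ids are densified and ordered by size.

## Marker statistics and the genescore

`find_markers` computes, per gene, `avg_logFC = ln(mean(expm1(x)) + 1)`
in-cluster minus the same out-of-cluster (pseudocount +1 inside each log),
and detection fractions `pct1`/`pct2` with "expressed" meaning value > 0
exactly. Genes are admitted at `avg_logFC ≥ 0.25` and `pct1 > 0.25`
(strict). P-values come from the two-sided Wilcoxon rank-sum test and are
Bonferroni-adjusted by the total gene count of the matrix.

The rank-sum p is **exact** for pooled samples of ≤ 25 values: the
permutation distribution of the midrank sum is built by subset-sum dynamic
programming (doubled ranks keep it on an integer lattice), and the
two-sided p is the probability of a deviation from the expectation at
least as large as observed. Beyond 25 the normal approximation with
tie-corrected variance and 0.5 continuity correction is used; its
pointwise error against enumeration can reach ~0.05–0.10 for groups of
size ≤ 8 (which is why the exact branch exists) and shrinks rapidly with
sample size.

The genescore is `avg_logFC * pct1 / max(pct2, 0.001)`. The 0.001 floor
keeps perfectly specific markers (pct2 = 0) finite; pct fields are
conventionally reported at 3-decimal resolution, making 0.001 the smallest
distinguishable nonzero value. A `fc_scale="linear"` flag substitutes
`exp(avg_logFC)`; the log scale is the default and the only one the
validation suite pins.

Gene-set (cell-cycle) scores are the mean expression of the set minus the
mean of control genes drawn per set gene from the same average-expression
bin (24 equal-occupancy bins, 100 controls per set gene, seeded). Control
pools exclude the set genes themselves — otherwise a set concentrated in a
few bins contaminates its own controls and cancels its signal.

Box-plot summaries use type-7 (linear interpolation) quartiles and Tukey
fences at 1.5 × IQR; whisker extremes exclude the flagged outliers.

## Cross-species integration

- **Shared feature space**: `(hvg_A ∪ hvg_B) ∩ genes_A ∩ genes_B`, each
  dataset z-scaled per gene over it.
- **Diagonal CCA**: SVD of `Z_A @ Z_B.T`. The canonical correlation of a
  component pair is the cosine of its two gene-space projections
  (`Z_A.T u` vs `Z_B.T v`) — exactly 1 when one dataset copies the other —
  and components are re-sorted by decreasing correlation so the reported
  sequence is monotone by construction. Cell rows are L2-normalized, making
  Euclidean neighbor queries equivalent to cosine ordering.
- **MNN anchors**: pair (a, b) is an anchor iff each is among the other's
  `k_anchor = 5` nearest cross-dataset cells; the per-side neighbor count
  saturates at the dataset size, so `k_anchor` ≥ both counts yields the
  complete cross-pair set. Anchor scores are the shared-neighbor overlap in
  the joint space (`k_score = 30`), min-max rescaled to [0, 1]. No anchor
  filtering step is applied; this is a minimal documented subset of the
  published anchor recipe, validated against planted truth rather than
  against any reference implementation.
- **Label transfer** follows the any-anchor rule: a B-cell acquires the
  reference label if at least one anchor partner carries it; cells
  qualifying for several targets are reported with all labels and a
  multi-label flag.
- **Correction**: each B-cell is shifted by a Gaussian-kernel weighted
  average (`exp(-0.5 (d/sd)^2)`, sd = 1 on the unit-norm embedding, weights
  normalized to sum 1) of its `k_weight = 100` nearest anchors'
  (A − B) difference vectors; A-cells are unchanged. This difference-vector
  smoothing in CCA space is sufficient for joint SNN clustering, the only
  downstream use; no corrected gene-space matrix is produced.
- **Cluster correlation**: Pearson r over the **intersection** of the two
  clusters' admitted marker genes (no zero-imputation for missing
  genescores; a union-with-zeros variant would be a caller-side transform
  of the tables), two-sided p from the t-transform with n − 2 df, flagged
  undefined below 3 shared genes.
- **Cluster score**: `score(cell) = Σ_g genescore_ref(g) * expr(cell, g)`
  over reference markers present in the dataset, with expression on the
  log-normalized scale (a z-scaled variant can be obtained by passing a
  scaled matrix wrapped as a `NormalizedMatrix`); missing markers are
  skipped and reported in a coverage attribute.

## Validation design and problem sizes

The planted-truth study (`homoglia.validation`) simulates ten dataset pairs
at the default conditions — 6 shared types, 200 cells/type/species, 1500
genes, 5 % markers/type at log effect 1.0, dispersion 0.1, one 5 % rare
type — and measures: the genescore-correlation argmax homology match rate,
per-cell cluster-score median separation, rare-type transfer
precision/recall, and best-bijective (Hungarian) joint-clustering accuracy
after anchor correction. Marker tables for the first two metrics are
computed on the planted type labels so the metrics isolate the scoring
machinery; the joint-clustering metric runs the full SNN + Leiden path.
These sizes keep the whole study around a minute on one CPU while leaving
each type with enough cells for stable detection fractions.

## Known limitations

- The vst fit uses lowess (local linear) rather than a local quadratic
  regression; rankings agree on well-behaved mean-variance relations but
  can differ for genes at the extremes of the mean range.
- kNN construction materializes the full distance matrix; beyond ~50k cells
  an approximate neighbor backend would be needed.
- The worked composition example uses the per-state counts 15/99/48
  (total 162); the companion trajectory analysis elsewhere reports 167
  cells for the same population — the printed per-state counts are taken
  as authoritative for the arithmetic and the inconsistency is inherited
  from the source data, not resolved here.
- Anchor scoring and label transfer have no anchor-filtering or weighting
  step; with strongly imbalanced types the any-anchor rule is permissive
  by design (a majority-vote mode would be stricter but is not what the
  homolog-prediction procedure specifies).
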