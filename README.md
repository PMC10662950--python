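# homoglia

Cross-species single-cell RNA-seq cluster homology analysis.

When the same developmental cell types exist in two species — say, cortical
progenitor subtypes in ferret and human — their scRNA-seq datasets cannot be
compared cluster-by-cluster directly: gene spaces differ, library depths
differ, and whole-transcriptome distances are dominated by species effects.
`homoglia` implements the standard cross-species workflow for establishing
cluster homology, built around a marker enrichment-and-specificity
statistic, the **genescore**:

```
genescore(g, cluster) = avg_logFC(g) * pct1(g) / max(pct2(g), 0.001)
```

where `avg_logFC` is the natural-log average fold change of gene *g* between
the cluster and all remaining cells, `pct1` the fraction of in-cluster cells
detecting *g*, and `pct2` the same fraction outside the cluster. Two
clusters from different species are scored as homologous when the Pearson
correlation of their genescore vectors over shared marker genes is high,
and individual cells are scored against a reference cluster by the
**cluster score** — the genescore-weighted linear combination of marker
expression — or mapped through **CCA + mutual-nearest-neighbor anchors**
(an anchor pair labels the partner cell with the reference cluster's
identity, e.g. predicting truncated-radial-glia-like cells in a species
where unbiased clustering cannot isolate them).

The package covers the full pipeline:

- `synthetic` — negative-binomial two-species simulator with planted
  homologous types, disjoint marker blocks, species shifts and a rare type;
  plus exact micro-fixtures and Hungarian-matching evaluation against truth.
- `preprocess` — 10x MTX triplet I/O, QC filtering (detected-gene bounds,
  mitochondrial fraction), log-normalization to 10,000 counts/cell, vst
  highly-variable-gene selection, z-scaling, PCA.
- `clustering` — shared-nearest-neighbor graph (Jaccard over kNN sets) and
  seeded Leiden/Louvain modularity clustering.
- `markers` — one-vs-rest Wilcoxon rank-sum marker tables (exact
  permutation p at small sample sizes), genescores, binned-control gene-set
  (cell-cycle) scores, Tukey box-plot summaries.
- `integrate` — shared ortholog feature space, diagonal CCA, MNN anchors,
  homolog label transfer, anchor-based embedding correction for joint
  clustering, cluster correlation and per-cell cluster scores.

## Worked example

```python
import pandas as pd
from homoglia import (
    SimulationConfig, simulate_two_species, process_species, compare_species,
    transfer_homolog_labels, cell_cluster_score,
)

counts_a, counts_b, truth = simulate_two_species(SimulationConfig(seed=1))
res_a = process_species(counts_a, seed=1, cluster_labels=truth.labels_a)
res_b = process_species(counts_b, seed=1, cluster_labels=truth.labels_b)
cmp = compare_species(res_a, res_b, seed=1)

# Which B-cluster does each A-cluster correlate with best?
corr = cmp.correlation[cmp.correlation["defined"]]
for ca, grp in corr.groupby("cluster_a"):
    best = grp.loc[grp["r"].idxmax()]
    print(f"{ca} -> {best['cluster_b']}  (r={best['r']:.2f}, n={int(best['n'])})")

# Predict rare-type-like cells in B from A's labels via anchors.
hits = transfer_homolog_labels(cmp.anchors, truth.labels_a, "rare")
true_rare = set(truth.labels_b[truth.labels_b == "rare"].index)
pred = set(hits["cell_b"])
print(f"transfer: {len(pred)} cells, precision "
      f"{len(pred & true_rare) / len(pred):.2f}, "
      f"recall {len(pred & true_rare) / len(true_rare):.2f}")
```

Output:

```
rare -> rare  (r=0.09, n=74)
type0 -> type0  (r=0.38, n=75)
type1 -> type1  (r=0.13, n=75)
type2 -> type2  (r=0.11, n=75)
type3 -> type3  (r=0.33, n=75)
type4 -> type4  (r=0.32, n=75)
transfer: 50 cells, precision 1.00, recall 0.94
```

Every planted type's best-correlated partner is its true homolog: the two
species share ~75 admitted markers per type, and only the homologous pair
correlates positively over them (the modest r values are expected here —
the simulator plants one uniform fold effect per marker block, so within
a block the genescore variation that the correlation can exploit is mostly
sampling noise; real marker sets carry a wide effect-size spectrum and
yield larger r). Anchor transfer recovers the planted 5 %-abundance rare
type with high precision — these are the two quantitative behaviors the
homology calls rest on.

A `homoglia` CLI mirrors the stages
(`simulate`, `preprocess`, `cluster`, `markers`, `integrate`, `correlate`,
`score`, `transfer`); run `homoglia --help`.

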