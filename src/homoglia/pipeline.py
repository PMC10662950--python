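"""End-to-end convenience drivers tying the stages together.

These wrap the module-level operations into the two workflows users run
most: per-dataset processing (QC -> normalize -> HVG -> scale -> PCA ->
SNN -> clusters) and the cross-species homology comparison (shared feature
space -> CCA -> MNN anchors -> label transfer / correction, plus genescore
correlation and per-cell cluster scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .clustering import build_snn, cluster_cells
from .containers import CountMatrix, Embedding, NormalizedMatrix
from .integrate import (
    AnchorSet,
    CCAEmbedding,
    build_shared_space,
    cca_embed,
    cluster_correlation_matrix,
    find_mnn_anchors,
    integrate_correct,
)
from .markers import compute_genescores, find_all_markers
from .preprocess import log_normalize, pca, qc_filter, scale_center, select_hvg

__all__ = ["SpeciesResult", "process_species", "CrossSpeciesResult", "compare_species"]


@dataclass
class SpeciesResult:
    """Per-dataset processing products."""

    norm: NormalizedMatrix
    hvg: list[str]
    embedding: Embedding
    clusters: pd.Series


def process_species(
    counts: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 5000,
    max_mito_frac: float = 0.30,
    n_hvg: int = 2000,
    n_pcs: int = 50,
    dims: int = 20,
    k: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
    cluster_labels: pd.Series | None = None,
) -> SpeciesResult:
    """QC, normalize, select HVG, embed and cluster one dataset.

    When ``cluster_labels`` is given (e.g. curated annotations), clustering
    is skipped and the labels are carried through after QC subsetting.
    """
    counts = qc_filter(counts, min_genes=min_genes, max_genes=max_genes,
                       max_mito_frac=max_mito_frac)
    norm = log_normalize(counts)
    hvg = select_hvg(norm, n=n_hvg)
    scaled = scale_center(norm, hvg)
    n_pcs = min(n_pcs, min(scaled.X.shape) - 1)
    emb = pca(scaled, n_pcs=n_pcs)
    if cluster_labels is not None:
        clusters = pd.Series(cluster_labels).loc[norm.cell_ids]
    else:
        snn = build_snn(emb, dims=min(dims, emb.n_components), k=k)
        clusters = cluster_cells(snn, resolution=resolution, seed=seed)
    return SpeciesResult(norm=norm, hvg=hvg, embedding=emb, clusters=clusters)


@dataclass
class CrossSpeciesResult:
    """Cross-species comparison products."""

    genescores_a: pd.DataFrame
    genescores_b: pd.DataFrame
    correlation: pd.DataFrame
    cca: CCAEmbedding
    anchors: AnchorSet
    joint_embedding: Embedding
    joint_clusters: pd.Series


def compare_species(
    res_a: SpeciesResult,
    res_b: SpeciesResult,
    n_cc: int = 20,
    k_anchor: int = 5,
    k_score: int = 30,
    k_weight: int = 100,
    resolution: float = 0.8,
    seed: int = 0,
    min_logfc: float = 0.25,
    min_pct: float = 0.25,
) -> CrossSpeciesResult:
    """Marker genescores, cluster correlation, anchors and joint clustering."""
    mk_a = find_all_markers(res_a.norm, res_a.clusters, min_logfc, min_pct)
    mk_b = find_all_markers(res_b.norm, res_b.clusters, min_logfc, min_pct)
    gs_a = compute_genescores(mk_a)
    gs_b = compute_genescores(mk_b)
    corr = cluster_correlation_matrix(gs_a, gs_b)
    space = build_shared_space(res_a.norm, res_b.norm, res_a.hvg, res_b.hvg)
    n_cc = min(n_cc, min(space.scaled_a.X.shape[0], space.scaled_b.X.shape[0],
                         len(space.features)))
    cca = cca_embed(space, n_cc=n_cc)
    anchors = find_mnn_anchors(cca, k_anchor=k_anchor, k_score=k_score)
    joint = integrate_correct(cca, anchors, k_weight=k_weight)
    snn = build_snn(joint, dims=joint.n_components, k=20)
    joint_clusters = cluster_cells(snn, resolution=resolution, seed=seed)
    return CrossSpeciesResult(
        genescores_a=gs_a,
        genescores_b=gs_b,
        correlation=corr,
        cca=cca,
        anchors=anchors,
        joint_embedding=joint,
        joint_clusters=joint_clusters,
    )
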