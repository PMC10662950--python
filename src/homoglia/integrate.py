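"""Cross-species integration: shared features, diagonal CCA, MNN anchors,
homolog-cell label transfer, anchor-based embedding correction, cluster
genescore correlation and per-cell cluster scores.

The anchor machinery is a minimal, documented subset of the established
CCA + mutual-nearest-neighbor integration recipe: per-gene scaling over a
shared ortholog feature space, a diagonal CCA computed as the SVD of the
cross-product of the two scaled matrices, L2 row normalization, mutual
k-nearest-neighbor anchor pairs, shared-neighbor anchor scores, and a
difference-vector correction that places both datasets in one space for
joint clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from sklearn.neighbors import NearestNeighbors

from .containers import Embedding, NormalizedMatrix, ScaledMatrix
from .preprocess import scale_center

__all__ = [
    "SharedFeatureSpace",
    "CCAEmbedding",
    "AnchorSet",
    "build_shared_space",
    "cca_embed",
    "find_mnn_anchors",
    "transfer_homolog_labels",
    "integrate_correct",
    "cluster_correlation",
    "cluster_correlation_matrix",
    "cell_cluster_score",
]


@dataclass
class SharedFeatureSpace:
    """Ortholog feature list with per-dataset scaled submatrices over it."""

    features: list[str]
    scaled_a: ScaledMatrix
    scaled_b: ScaledMatrix


@dataclass
class CCAEmbedding:
    """Per-dataset cell coordinates in the joint CCA space.

    Rows are L2-normalized; ``correlations`` holds the canonical
    correlation of each component pair, non-increasing in [0, 1].
    """

    coords_a: np.ndarray
    coords_b: np.ndarray
    cell_ids_a: pd.Index
    cell_ids_b: pd.Index
    correlations: np.ndarray


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor cross-dataset cell pairs with scores in [0, 1]."""

    pairs: pd.DataFrame  # columns: cell_a, cell_b, score
    k_anchor: int
    k_score: int

    def __len__(self) -> int:
        return len(self.pairs)


def build_shared_space(
    norm_a: NormalizedMatrix,
    norm_b: NormalizedMatrix,
    hvg_a,
    hvg_b,
    clip: float = 10.0,
) -> SharedFeatureSpace:
    """Features = (hvg_a | hvg_b) & genes_a & genes_b, scaled per dataset.

    Order is deterministic: hvg_a order first, then hvg_b novelties.
    """
    genes_a, genes_b = set(norm_a.gene_ids), set(norm_b.gene_ids)
    if not genes_a & genes_b:
        raise ValueError("gene name spaces of the two datasets are disjoint")
    union = list(dict.fromkeys(list(hvg_a) + list(hvg_b)))
    features = [g for g in union if g in genes_a and g in genes_b]
    if not features:
        raise ValueError("no shared feature: HVG union does not intersect both gene spaces")
    return SharedFeatureSpace(
        features=features,
        scaled_a=scale_center(norm_a, features, clip=clip),
        scaled_b=scale_center(norm_b, features, clip=clip),
    )


def cca_embed(space: SharedFeatureSpace, n_cc: int = 20) -> CCAEmbedding:
    """Diagonal CCA: SVD of the cross-product of the two scaled matrices.

    The per-component canonical correlation is the cosine between the two
    gene-space projections ``Za.T @ u`` and ``Zb.T @ v``; components are
    ordered by decreasing correlation.  Cell rows are L2-normalized.
    """
    Za, Zb = space.scaled_a.X, space.scaled_b.X
    limit = min(Za.shape[0], Zb.shape[0], Za.shape[1])
    if n_cc > limit:
        raise ValueError(f"n_cc={n_cc} exceeds min(cell counts, feature count)={limit}")
    K = Za @ Zb.T
    U, s, Vt = scipy.linalg.svd(K, full_matrices=False)
    U, V = U[:, :n_cc], Vt[:n_cc].T.copy()
    # Deterministic sign: largest-magnitude A-side entry positive per component.
    for k in range(n_cc):
        j = np.argmax(np.abs(U[:, k]))
        if U[j, k] < 0:
            U[:, k] *= -1
            V[:, k] *= -1
    pa = Za.T @ U  # genes x n_cc
    pb = Zb.T @ V
    denom = np.linalg.norm(pa, axis=0) * np.linalg.norm(pb, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, s[:n_cc] / denom, 0.0)
    corr = np.clip(corr, 0.0, 1.0)
    order = np.lexsort((np.arange(n_cc), -corr))
    U, V, corr = U[:, order], V[:, order], corr[order]

    def l2(M: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(M, axis=1, keepdims=True)
        return M / np.where(nrm > 0, nrm, 1.0)

    return CCAEmbedding(
        coords_a=l2(U),
        coords_b=l2(V),
        cell_ids_a=space.scaled_a.cell_ids,
        cell_ids_b=space.scaled_b.cell_ids,
        correlations=corr,
    )


def find_mnn_anchors(
    emb: CCAEmbedding, k_anchor: int = 5, k_score: int = 30
) -> AnchorSet:
    """Mutual k-nearest-neighbor cross-dataset cell pairs in CCA space.

    A pair (a, b) is an anchor iff b is among the ``k_anchor`` nearest
    B-cells to a and a is among the ``k_anchor`` nearest A-cells to b.
    The anchor score is the shared-neighbor overlap of the pair in the
    joint space (``k_score`` neighbors), min-max rescaled to [0, 1].
    """
    A, B = emb.coords_a, emb.coords_b
    n_a, n_b = A.shape[0], B.shape[0]
    if k_anchor < 1 or k_anchor > max(n_a, n_b):
        raise ValueError(f"k_anchor={k_anchor} exceeds max cell count {max(n_a, n_b)}")
    # k saturates at the dataset size on each side, so k_anchor >= both
    # counts yields the complete cross-pair set.
    nn_b = NearestNeighbors(n_neighbors=min(k_anchor, n_b)).fit(B)
    ab = nn_b.kneighbors(A, return_distance=False)  # for each a: k nearest b
    nn_a = NearestNeighbors(n_neighbors=min(k_anchor, n_a)).fit(A)
    ba = nn_a.kneighbors(B, return_distance=False)
    ba_sets = [set(row) for row in ba]
    pairs = [
        (i, int(j))
        for i in range(n_a)
        for j in ab[i]
        if i in ba_sets[int(j)]
    ]
    if pairs:
        joint = np.vstack([A, B])
        k_sc = min(k_score, joint.shape[0] - 1)
        nn_joint = NearestNeighbors(n_neighbors=k_sc + 1).fit(joint)
        nbrs = nn_joint.kneighbors(joint, return_distance=False)[:, 1:]
        nbr_sets = [set(row) for row in nbrs]
        raw = np.array(
            [len(nbr_sets[i] & nbr_sets[n_a + j]) / k_sc for i, j in pairs]
        )
        span = raw.max() - raw.min()
        score = (raw - raw.min()) / span if span > 0 else np.ones_like(raw)
    else:
        score = np.array([])
    df = pd.DataFrame(
        {
            "cell_a": [emb.cell_ids_a[i] for i, _ in pairs],
            "cell_b": [emb.cell_ids_b[j] for _, j in pairs],
            "score": score,
        }
    )
    return AnchorSet(pairs=df, k_anchor=k_anchor, k_score=k_score)


def transfer_homolog_labels(
    anchors: AnchorSet, labels_a: pd.Series, target_cluster
) -> pd.DataFrame:
    """Label B-cells homologous to one or more reference A-clusters.

    A B-cell is included iff at least one of its anchor partners carries a
    target cluster label.  Cells qualifying for multiple target clusters
    carry all labels and ``multi=True``.
    """
    labels_a = pd.Series(labels_a)
    targets = [target_cluster] if np.isscalar(target_cluster) or isinstance(
        target_cluster, str
    ) else list(target_cluster)
    known = set(labels_a.unique())
    unknown = [t for t in targets if t not in known]
    if unknown:
        raise ValueError(f"unknown target cluster(s) {unknown}; known: {sorted(map(str, known))}")
    if len(anchors.pairs) == 0:
        return pd.DataFrame(columns=["cell_b", "labels", "multi"])
    pairs = anchors.pairs
    missing = set(pairs["cell_a"]) - set(labels_a.index)
    if missing:
        raise ValueError(f"labels_a does not cover anchor A-cells, e.g. {sorted(missing)[:3]}")
    anno = pairs.assign(label=labels_a.loc[pairs["cell_a"]].to_numpy())
    anno = anno[anno["label"].isin(targets)]
    got = anno.groupby("cell_b")["label"].agg(lambda s: sorted(set(s)))
    out = pd.DataFrame(
        {
            "cell_b": got.index,
            "labels": got.to_numpy(),
            "multi": [len(v) > 1 for v in got],
        }
    ).reset_index(drop=True)
    return out


def integrate_correct(
    emb: CCAEmbedding, anchors: AnchorSet, k_weight: int = 100, sd: float = 1.0
) -> Embedding:
    """Shift B-cells by smoothed anchor difference vectors; A-cells unchanged.

    Each B-cell moves by a weighted average of the (A - B) coordinate
    differences of its ``k_weight`` nearest anchors (distance measured to
    the anchors' B-side cells), with Gaussian-kernel weights
    ``exp(-0.5 (d / sd)^2)`` normalized to sum 1.  The returned joint
    embedding concatenates A then corrected B and is suitable for joint
    SNN clustering.
    """
    if len(anchors.pairs) == 0:
        raise ValueError("anchor set is empty")
    idx_a = emb.cell_ids_a.get_indexer(anchors.pairs["cell_a"])
    idx_b = emb.cell_ids_b.get_indexer(anchors.pairs["cell_b"])
    diff = emb.coords_a[idx_a] - emb.coords_b[idx_b]  # per-anchor correction
    anchor_pos = emb.coords_b[idx_b]
    k = min(k_weight, len(anchors.pairs))
    nn = NearestNeighbors(n_neighbors=k).fit(anchor_pos)
    dist, nbr = nn.kneighbors(emb.coords_b)
    w = np.exp(-0.5 * (dist / sd) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    correction = np.einsum("ij,ijk->ik", w, diff[nbr])
    corrected_b = emb.coords_b + correction
    coords = np.vstack([emb.coords_a, corrected_b])
    cell_ids = emb.cell_ids_a.append(emb.cell_ids_b)
    return Embedding(coords=coords, cell_ids=cell_ids)


def cluster_correlation(
    gs_a: pd.DataFrame,
    gs_b: pd.DataFrame,
    cluster_a,
    cluster_b,
    min_shared: int = 3,
) -> dict:
    """Pearson correlation of genescores over markers shared by two clusters.

    Returns ``{"r", "p", "n", "defined"}``; entries with fewer than
    ``min_shared`` shared marker genes are flagged undefined rather than
    erroring.  p is two-sided from the t-transform with n - 2 df.
    """
    sub_a = gs_a[gs_a["cluster"] == cluster_a].set_index("gene")["genescore"]
    sub_b = gs_b[gs_b["cluster"] == cluster_b].set_index("gene")["genescore"]
    shared = sub_a.index.intersection(sub_b.index)
    n = len(shared)
    if n < min_shared:
        return {"r": np.nan, "p": np.nan, "n": n, "defined": False}
    va, vb = sub_a.loc[shared].to_numpy(), sub_b.loc[shared].to_numpy()
    if np.std(va) == 0 or np.std(vb) == 0:
        return {"r": np.nan, "p": np.nan, "n": n, "defined": False}
    r, p = stats.pearsonr(va, vb)
    return {"r": float(r), "p": float(p), "n": n, "defined": True}


def cluster_correlation_matrix(
    gs_a: pd.DataFrame, gs_b: pd.DataFrame, min_shared: int = 3
) -> pd.DataFrame:
    """Long-form table of :func:`cluster_correlation` over all cluster pairs."""
    rows = []
    for ca in pd.unique(gs_a["cluster"]):
        for cb in pd.unique(gs_b["cluster"]):
            entry = cluster_correlation(gs_a, gs_b, ca, cb, min_shared)
            rows.append({"cluster_a": ca, "cluster_b": cb, **entry})
    return pd.DataFrame(rows)


def cell_cluster_score(
    norm: NormalizedMatrix, gs_ref: pd.DataFrame, ref_cluster
) -> pd.Series:
    """Per-cell score for a reference cluster: sum of genescore x expression.

    The sum runs over the reference cluster's marker genes present in this
    dataset; missing markers are skipped and reported in
    ``result.attrs['coverage']``.
    """
    sub = gs_ref[gs_ref["cluster"] == ref_cluster]
    if sub.empty:
        raise ValueError(f"reference cluster {ref_cluster!r} has no genescore rows")
    weights = sub.set_index("gene")["genescore"]
    present = [g for g in weights.index if g in set(norm.gene_ids)]
    if not present:
        raise ValueError(
            f"no marker of cluster {ref_cluster!r} is present in the dataset"
        )
    idx = norm.gene_ids.get_indexer(present)
    w = weights.loc[present].to_numpy()
    score = np.asarray(norm.X[:, idx].todense()) @ w
    out = pd.Series(score, index=norm.cell_ids, name=f"score_{ref_cluster}")
    out.attrs["coverage"] = {
        "n_markers": int(len(weights)),
        "n_present": int(len(present)),
        "missing": sorted(set(weights.index) - set(present)),
    }
    return out
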