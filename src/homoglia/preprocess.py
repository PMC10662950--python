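"""QC filtering, log-normalization, HVG selection, scaling and PCA.

The processing conventions follow the standard droplet scRNA-seq recipe:
cells are kept when their detected-gene count lies strictly between
``min_genes`` and ``max_genes`` and their mitochondrial count fraction is
below ``max_mito_frac``; genes must be detected in at least
``min_cells_per_gene`` cells (the gene filter runs first).  Normalization
scales each cell to a fixed total (10,000 by default) and applies
``ln(1 + x)``.  Highly variable genes are ranked by standardized variance
under the variance-stabilizing (vst) scheme.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import CountMatrix, Embedding, NormalizedMatrix, ScaledMatrix

__all__ = [
    "qc_filter",
    "log_normalize",
    "select_hvg",
    "scale_center",
    "pca",
    "EmptyResultError",
]

log = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """QC filtering removed every cell."""


def qc_filter(
    counts: CountMatrix,
    min_genes: int = 200,
    max_genes: int = 5000,
    min_cells_per_gene: int = 3,
    max_mito_frac: float = 0.30,
) -> CountMatrix:
    """Filter genes then cells by the standard droplet QC rules.

    Retained cells have a detected-gene count strictly greater than
    ``min_genes`` and strictly less than ``max_genes``, and a mitochondrial
    count fraction (on raw counts) strictly below ``max_mito_frac``.
    Retained genes are detected in at least ``min_cells_per_gene`` cells;
    the gene filter is applied before the cell filters.
    """
    if min_genes <= 0 or max_genes <= 0 or min_cells_per_gene <= 0:
        raise ValueError("QC thresholds must be positive")
    X = counts.X
    # Mito fraction on raw counts of the *unfiltered* matrix.
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito = np.asarray(X[:, counts.mito_gene_flags].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)

    gene_mask = np.asarray((X > 0).sum(axis=0)).ravel() >= min_cells_per_gene
    Xg = X[:, gene_mask]
    detected = np.asarray((Xg > 0).sum(axis=1)).ravel()
    cell_mask = (detected > min_genes) & (detected < max_genes) & (mito_frac < max_mito_frac)

    log.info(
        "qc_filter: kept %d/%d genes (detected in >= %d cells); "
        "kept %d/%d cells (%d < genes < %d, mito < %.0f%%)",
        gene_mask.sum(), counts.n_genes, min_cells_per_gene,
        cell_mask.sum(), counts.n_cells, min_genes, max_genes, 100 * max_mito_frac,
    )
    if not cell_mask.any():
        raise EmptyResultError("QC filtering removed every cell")
    return counts.subset(cell_mask, gene_mask)


def log_normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Per-cell total scaling to ``scale_factor`` followed by ln(1 + x).

    value = ln(1 + scale_factor * count / cell_total).  Zero-total cells are
    rejected with an error naming the first offending cell.
    """
    totals = np.asarray(counts.X.sum(axis=1)).ravel().astype(float)
    if (totals == 0).any():
        bad = counts.cell_ids[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts; run qc_filter first")
    X = counts.X.tocoo()
    data = np.log1p(scale_factor * X.data / totals[X.row])
    norm = sp.csr_matrix((data, (X.row, X.col)), shape=X.shape)
    return NormalizedMatrix(
        norm,
        counts.cell_ids,
        counts.gene_ids,
        scale_factor=scale_factor,
        counts=counts.X,
        cell_meta=counts.cell_meta,
    )


def _vst_standardized_variance(counts: sp.spmatrix) -> np.ndarray:
    """Standardized per-gene variance of raw counts under the vst scheme.

    Fits log10(variance) on log10(mean) with a local linear regression
    (span 0.3), standardizes counts by the fitted expected standard
    deviation, clips at sqrt(n_cells), and returns the variance of the
    clipped standardized values per gene.
    """
    X = sp.csc_matrix(counts)
    n = X.shape[0]
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / (n - 1)
    std_var = np.zeros(X.shape[1])
    ok = var > 0
    if ok.sum() >= 2:
        lx, ly = np.log10(mean[ok]), np.log10(var[ok])
        fitted = lowess(ly, lx, frac=0.3, xvals=lx)
        bad = ~np.isfinite(fitted)
        if bad.any():
            # lowess interpolation can drop points (duplicate/extreme x);
            # fall back to linear interpolation of the fitted curve.
            good = np.isfinite(fitted)
            order = np.argsort(lx[good])
            fitted[bad] = np.interp(lx[bad], lx[good][order], fitted[good][order])
        exp_sd = np.sqrt(10.0**fitted)
        clip = np.sqrt(n)
        # Clipped standardized variance computed per gene without densifying
        # the whole matrix: nonzero entries per gene + the zero mass.
        idx_ok = np.where(ok)[0]
        for j, g in enumerate(idx_ok):
            vals = X[:, g].toarray().ravel()
            z = np.clip((vals - mean[g]) / exp_sd[j], -clip, clip)
            std_var[g] = z.var(ddof=1)
    return std_var


def select_hvg(norm: NormalizedMatrix, n: int = 2000) -> list[str]:
    """Rank genes by vst standardized variance; return the top ``min(n, n_genes)``.

    Operates on the raw count moments carried by the normalized matrix.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if norm.n_cells < 3:
        raise ValueError("HVG selection needs at least 3 cells")
    if norm.counts is None:
        raise ValueError("normalized matrix does not carry its parent raw counts")
    std_var = _vst_standardized_variance(norm.counts)
    # Stable ranking: descending standardized variance, gene order breaks ties.
    order = np.lexsort((np.arange(len(std_var)), -std_var))
    return [norm.gene_ids[i] for i in order[: min(n, norm.n_genes)]]


def scale_center(
    norm: NormalizedMatrix, genes: list[str], clip: float = 10.0
) -> ScaledMatrix:
    """Per-gene z-score (population sd) over ``genes``, clipped at +/- ``clip``.

    Zero-variance genes map to all-zeros.
    """
    if len(genes) == 0:
        raise ValueError("gene list must be nonempty")
    missing = set(genes) - set(norm.gene_ids)
    if missing:
        raise ValueError(f"genes not in matrix: {sorted(missing)[:5]}")
    idx = norm.gene_ids.get_indexer(genes)
    X = np.asarray(norm.X[:, idx].todense(), dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population sd
    Z = np.zeros_like(X)
    nz = sd > 0
    Z[:, nz] = np.clip((X[:, nz] - mean[nz]) / sd[nz], -clip, clip)
    return ScaledMatrix(Z, norm.cell_ids, pd.Index(genes), clip_bound=clip)


def _deterministic_sign(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip component signs so the largest-magnitude loading is positive."""
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] *= -1
            U[:, k] *= -1
    return U, V


def pca(scaled: ScaledMatrix, n_pcs: int = 50) -> Embedding:
    """Truncated SVD of the scaled matrix with a deterministic sign convention.

    Returns cell coordinates (U * s), per-component variance shares, and
    orthonormal gene loadings.
    """
    X = scaled.X
    if n_pcs > min(X.shape):
        raise ValueError(
            f"n_pcs={n_pcs} exceeds min(n_cells, n_genes)={min(X.shape)}"
        )
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    U, V = _deterministic_sign(U[:, :n_pcs], Vt[:n_pcs].T.copy())
    n = X.shape[0]
    total_var = (X**2).sum() / (n - 1) if n > 1 else np.inf
    var_share = (s[:n_pcs] ** 2 / (n - 1)) / total_var if np.isfinite(total_var) else s[:n_pcs] * 0
    return Embedding(
        coords=U * s[:n_pcs],
        cell_ids=scaled.cell_ids,
        variance_ratio=np.asarray(var_share),
        loadings=V,
        gene_ids=scaled.gene_ids,
    )
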