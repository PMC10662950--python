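"""In-memory containers for the pipeline.

All matrices are oriented cells x genes internally, regardless of the
genes x cells orientation used by the 10x on-disk triplet format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "ScaledMatrix",
    "Embedding",
    "MITO_PREFIXES",
]

#: Gene-name prefixes treated as mitochondrial when no explicit flags are given.
MITO_PREFIXES = ("MT-", "mt-")


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique()[:5].tolist()
        raise ValueError(f"duplicate {what} identifiers: {dup}")


@dataclass
class CountMatrix:
    """UMI counts, cells x genes, with per-cell metadata.

    Parameters
    ----------
    X
        Sparse (CSR) or dense nonnegative integer counts, cells x genes.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    cell_meta
        Optional per-cell table (species, stage, batch, ...) indexed by cell id.
    mito_gene_flags
        Boolean per gene; defaults to a gene-name prefix match against
        :data:`MITO_PREFIXES`.
    """

    X: sp.spmatrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    cell_meta: pd.DataFrame | None = None
    mito_gene_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.cell_ids = pd.Index(self.cell_ids, dtype=object)
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        if self.X.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.X.nnz and self.X.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.X.dtype, np.integer):
            data = self.X.data
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integer valued")
            self.X = self.X.astype(np.int64)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)
        else:
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
        if self.mito_gene_flags is None:
            self.mito_gene_flags = np.array(
                [g.startswith(MITO_PREFIXES) for g in self.gene_ids], dtype=bool
            )
        else:
            self.mito_gene_flags = np.asarray(self.mito_gene_flags, dtype=bool)
            if self.mito_gene_flags.shape != (len(self.gene_ids),):
                raise ValueError("mito_gene_flags length does not match gene count")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrix":
        cm = np.ones(self.n_cells, bool) if cell_mask is None else np.asarray(cell_mask)
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask)
        return CountMatrix(
            self.X[cm][:, gm],
            self.cell_ids[cm],
            self.gene_ids[gm],
            self.cell_meta.loc[self.cell_ids[cm]],
            self.mito_gene_flags[gm],
        )

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes)."""
        import anndata

        return anndata.AnnData(
            X=self.X.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame({"mito": self.mito_gene_flags}, index=self.gene_ids),
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression ln(1 + scale_factor * count / cell_total).

    Keeps a handle on the parent raw counts: highly-variable-gene selection
    operates on raw count moments while sharing this object's index space.
    """

    X: sp.spmatrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    scale_factor: float = 10_000.0
    counts: sp.spmatrix | None = None
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.cell_ids = pd.Index(self.cell_ids, dtype=object)
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        if self.X.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("normalized matrix shape mismatch")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.cell_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())


@dataclass
class ScaledMatrix:
    """Per-gene z-scored expression over a gene subset, clipped at +/- clip_bound."""

    X: np.ndarray
    cell_ids: pd.Index
    gene_ids: pd.Index
    clip_bound: float = 10.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.cell_ids = pd.Index(self.cell_ids, dtype=object)
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        if self.X.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("scaled matrix shape mismatch")


@dataclass
class Embedding:
    """Low-dimensional cell coordinates (PCA or CCA).

    ``coords`` is cells x components; ``variance_ratio`` holds the share of
    total variance per component (PCA) or canonical correlations (CCA);
    ``loadings`` is genes x components where applicable.
    """

    coords: np.ndarray
    cell_ids: pd.Index
    variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))
    loadings: np.ndarray | None = None
    gene_ids: pd.Index | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.cell_ids = pd.Index(self.cell_ids, dtype=object)
        if self.coords.shape[0] != len(self.cell_ids):
            raise ValueError("embedding row count does not match cell ids")

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]
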