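"""Reading and writing the 10x Genomics MTX triplet and flat-table outputs.

On disk the triplet follows the CellRanger v2 dialect: ``matrix.mtx`` is
genes x cells MatrixMarket, ``genes.tsv`` has two tab-separated columns
(gene id, gene symbol) and ``barcodes.tsv`` one barcode per line.  In memory
everything is cells x genes (see :mod:`homoglia.containers`).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "read_10x_mtx",
    "write_10x_mtx",
    "mtx_triplet_bytes",
    "MissingFileError",
    "DimensionMismatchError",
    "NonIntegerEntriesError",
]


class MissingFileError(FileNotFoundError):
    """A required triplet file is absent."""


class DimensionMismatchError(ValueError):
    """MTX header dimensions disagree with the feature/barcode files."""


class NonIntegerEntriesError(ValueError):
    """The count matrix contains non-integer entries."""


def _find_triplet(path: Path) -> tuple[Path, Path, Path]:
    mtx = path / "matrix.mtx"
    barcodes = path / "barcodes.tsv"
    genes = path / "genes.tsv"
    if not genes.exists() and (path / "features.tsv").exists():
        genes = path / "features.tsv"
    for f in (mtx, genes, barcodes):
        if not f.exists():
            raise MissingFileError(f"missing triplet file: {f}")
    return mtx, genes, barcodes


def read_10x_mtx(path: str | Path) -> CountMatrix:
    """Read a 10x MTX triplet directory into a :class:`CountMatrix`.

    Raises
    ------
    MissingFileError
        if matrix.mtx, genes/features.tsv or barcodes.tsv is absent.
    DimensionMismatchError
        if the MTX header disagrees with the feature/barcode line counts.
    NonIntegerEntriesError
        if any stored entry is not an integer.
    """
    path = Path(path)
    mtx_file, genes_file, barcodes_file = _find_triplet(path)
    mat = scipy.io.mmread(str(mtx_file))  # genes x cells on disk
    genes = pd.read_csv(genes_file, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_file, sep="\t", header=None)
    n_genes, n_cells = mat.shape
    if len(genes) != n_genes:
        raise DimensionMismatchError(
            f"matrix declares {n_genes} genes but {genes_file.name} has {len(genes)} rows"
        )
    if len(barcodes) != n_cells:
        raise DimensionMismatchError(
            f"matrix declares {n_cells} cells but {barcodes_file.name} has {len(barcodes)} rows"
        )
    data = sp.coo_matrix(mat).data
    if data.size and not np.allclose(data, np.round(data)):
        raise NonIntegerEntriesError(f"{mtx_file} contains non-integer entries")
    gene_ids = pd.Index(genes.iloc[:, 0].astype(str))
    cell_ids = pd.Index(barcodes.iloc[:, 0].astype(str))
    X = sp.csr_matrix(mat.T).astype(np.int64)  # transpose to cells x genes
    return CountMatrix(X, cell_ids, gene_ids)


def write_10x_mtx(counts: CountMatrix, path: str | Path) -> None:
    """Write a CellRanger v2 style triplet (genes x cells) under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "matrix.mtx").write_bytes(_mtx_bytes(counts))
    genes = pd.DataFrame({"id": counts.gene_ids, "symbol": counts.gene_ids})
    genes.to_csv(path / "genes.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )


def _mtx_bytes(counts: CountMatrix) -> bytes:
    coo = sp.coo_matrix(counts.X.T)  # genes x cells on disk
    # Canonical ordering (column-major, like CellRanger) for byte-stable output.
    order = np.lexsort((coo.row, coo.col))
    buf = _io.BytesIO()
    buf.write(b"%%MatrixMarket matrix coordinate integer general\n")
    buf.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n".encode())
    rows, cols, data = coo.row[order] + 1, coo.col[order] + 1, coo.data[order]
    lines = "\n".join(f"{r} {c} {d}" for r, c, d in zip(rows, cols, data))
    buf.write(lines.encode())
    buf.write(b"\n")
    return buf.getvalue()


def mtx_triplet_bytes(counts: CountMatrix) -> bytes:
    """Deterministic byte serialization of the full triplet (for equality checks)."""
    genes = "\n".join(f"{g}\t{g}" for g in counts.gene_ids)
    cells = "\n".join(counts.cell_ids)
    return _mtx_bytes(counts) + genes.encode() + b"\n" + cells.encode() + b"\n"
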