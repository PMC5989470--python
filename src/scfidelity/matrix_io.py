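"""I/O for UMI count matrices, gene lists, and result tables.

Two on-disk dialects are supported for digital gene expression (DGE) matrices:

* dense tab-separated tables, genes in rows and cells in columns by default
  (the common DGE convention), with the top-left header cell ``GENE``;
* MatrixMarket coordinate triplets (genes x cells, 1-based indices) with
  ``barcodes.tsv`` / ``genes.tsv`` sidecar files, one identifier per line.

The canonical in-memory layout is always cells x genes.  Loading never
normalizes or otherwise alters counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "GeneList",
    "read_dense_dge",
    "write_dense_dge",
    "read_sparse_triplet",
    "write_sparse_triplet",
    "read_gene_list",
    "write_gene_list",
]


@dataclass
class CountMatrix:
    """Cells x genes matrix of non-negative integer UMI counts.

    ``counts`` is a pandas DataFrame whose index holds the unique cell
    barcodes and whose columns hold the unique gene symbols (case-sensitive
    mm10-style symbols; no alias resolution is attempted).
    """

    counts: pd.DataFrame
    sample_label: str = ""

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell barcodes: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at cell {counts.index[r]!r}, gene {counts.columns[c]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            if not np.array_equal(values, np.round(values)):
                bad = np.argwhere(values != np.round(values))[0]
                r, c = bad
                raise ValueError(
                    f"non-integer count {values[r, c]} at cell "
                    f"{counts.index[r]!r}, gene {counts.columns[c]!r}"
                )
            self.counts = counts.astype(np.int64)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class GeneList:
    """Ordered, duplicate-free list of gene symbols with a name."""

    name: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g in seen:
                raise ValueError(f"duplicate gene symbol in list {self.name!r}: {g!r}")
            seen.add(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def read_dense_dge(
    path: str | Path, orientation: str = "genes_by_cells", sample_label: str = ""
) -> CountMatrix:
    """Read a dense tab-separated DGE table.

    ``orientation`` names the on-disk layout; the result is always cells x
    genes.  Non-integer or negative entries raise with their coordinates.
    """
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError("orientation must be 'genes_by_cells' or 'cells_by_genes'")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric entry in {path}: {exc}") from exc
    if orientation == "genes_by_cells":
        numeric = numeric.T
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    numeric.index.name = None
    numeric.columns.name = None
    return CountMatrix(numeric, sample_label=sample_label or Path(path).stem)


def write_dense_dge(m: CountMatrix, path: str | Path, orientation: str = "genes_by_cells") -> None:
    """Write a dense DGE table; top-left header cell is ``GENE``."""
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValueError("orientation must be 'genes_by_cells' or 'cells_by_genes'")
    df = m.counts.T if orientation == "genes_by_cells" else m.counts
    df = df.copy()
    df.index.name = "GENE" if orientation == "genes_by_cells" else "BARCODE"
    df.to_csv(path, sep="\t")


def read_sparse_triplet(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    genes_path: str | Path,
    sample_label: str = "",
) -> CountMatrix:
    """Read a MatrixMarket coordinate triplet (genes x cells on disk).

    Sidecar files carry one barcode / gene symbol per line; their lengths
    must match the dimension header.  Unlisted coordinates are zero.
    """
    mat = scipy.io.mmread(str(matrix_path))
    barcodes = _read_lines(barcodes_path)
    genes = _read_lines(genes_path)
    n_genes, n_cells = mat.shape
    if n_genes != len(genes) or n_cells != len(barcodes):
        raise ValueError(
            f"dimension header {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    dense = np.asarray(scipy.sparse.coo_matrix(mat).todense()).T
    df = pd.DataFrame(dense, index=barcodes, columns=genes)
    return CountMatrix(df, sample_label=sample_label)


def write_sparse_triplet(
    m: CountMatrix,
    matrix_path: str | Path,
    barcodes_path: str | Path,
    genes_path: str | Path,
) -> None:
    sparse = scipy.sparse.coo_matrix(m.counts.to_numpy().T)
    scipy.io.mmwrite(str(matrix_path), sparse, field="integer")
    Path(barcodes_path).write_text("\n".join(m.cell_ids) + "\n")
    Path(genes_path).write_text("\n".join(m.gene_ids) + "\n")


def _read_lines(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_gene_list(path: str | Path, name: str | None = None) -> GeneList:
    """Read a plain-text gene list, one symbol per line, order-preserving.

    Blank lines are ignored; surrounding whitespace is stripped; duplicates
    and empty files raise.
    """
    genes = _read_lines(path)
    if not genes:
        raise ValueError(f"gene list {path} is empty")
    return GeneList(name=name or Path(path).stem, genes=genes)


def write_gene_list(gl: GeneList | Sequence[str], path: str | Path) -> None:
    genes = list(gl.genes) if isinstance(gl, GeneList) else list(gl)
    Path(path).write_text("\n".join(genes) + "\n")
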