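"""Readers and writers for 10x-style count matrices, gene-set files, and TF lists.

The on-disk layout mirrors CellRanger output: ``matrix.mtx`` (Matrix Market,
genes x cells), ``features.tsv`` (1-3 columns: id / symbol / type) and
``barcodes.tsv``, each optionally gzipped. Gene sets and transcription-factor
lists are plain text, one symbol per line.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneSetPair",
    "TFList",
    "FormatError",
    "read_10x_mtx",
    "write_10x_mtx",
    "read_gene_sets",
    "read_tf_list",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of raw UMI counts.

    Attributes
    ----------
    values : scipy.sparse.csr_matrix
        Non-negative integer counts, genes in rows, cells in columns.
    gene_ids : pandas.Index
        Unique gene symbols, one per row.
    cell_ids : pandas.Index
        Unique cell barcodes, one per column.
    """

    values: sp.csr_matrix
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise FormatError(
                f"gene id list has {len(self.gene_ids)} entries for {n_genes} rows"
            )
        if len(self.cell_ids) != n_cells:
            raise FormatError(
                f"cell id list has {len(self.cell_ids)} entries for {n_cells} columns"
            )
        if not self.gene_ids.is_unique:
            raise FormatError("gene ids are not unique")
        if not self.cell_ids.is_unique:
            raise FormatError("cell ids are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("count matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Return a new CountMatrix keeping the cells where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return CountMatrix(self.values[:, mask], self.gene_ids, self.cell_ids[mask])


@dataclass
class GeneSetPair:
    """S-phase and G2/M gene lists used by the cell-cycle permutation test."""

    s_genes: list[str]
    g2m_genes: list[str]

    def __post_init__(self) -> None:
        if not self.s_genes or not self.g2m_genes:
            raise FormatError("gene sets must be non-empty")
        overlap = set(self.s_genes) & set(self.g2m_genes)
        if overlap:
            raise FormatError(
                "S and G2/M gene sets overlap (the permutation test assumes "
                f"disjoint sets): {sorted(overlap)}"
            )


@dataclass
class TFList:
    """Set of transcription-factor gene symbols."""

    symbols: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.symbols = frozenset(self.symbols)
        if not self.symbols:
            raise FormatError("TF list is empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_file(directory: Path, stem: str) -> Path:
    """Locate ``stem`` or ``stem.gz`` in directory; CellRanger v2 uses genes.tsv."""
    candidates = [stem, stem + ".gz"]
    if stem == "features.tsv":
        candidates += ["genes.tsv", "genes.tsv.gz"]
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}[.gz] in {directory}")


def _deduplicate(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate symbols deterministically with a -1, -2 ... suffix."""
    seen: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            out.append(f"{s}-{seen[s]}")
        else:
            seen[s] = 0
            out.append(s)
    return out


def read_10x_mtx(directory: str | os.PathLike) -> CountMatrix:
    """Read a 10x-layout directory (matrix.mtx + features.tsv + barcodes.tsv).

    Plain and gzipped variants are both accepted. Features files may have
    1-3 tab-separated columns; the symbol column (second if present, else
    first) is used as the gene identifier. Duplicate symbols are suffixed
    ``-1``, ``-2``, ... in file order.
    """
    directory = Path(directory)
    mtx_path = _find_file(directory, "matrix.mtx")
    feat_path = _find_file(directory, "features.tsv")
    bc_path = _find_file(directory, "barcodes.tsv")

    with _open_maybe_gz(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)

    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    symbol_col = 1 if feats.shape[1] >= 2 else 0
    symbols = feats[symbol_col].str.strip().tolist()
    barcodes = pd.read_csv(bc_path, sep="\t", header=None, dtype=str)[0].str.strip().tolist()

    if len(symbols) != mat.shape[0]:
        raise FormatError(
            f"{feat_path.name} lists {len(symbols)} features but "
            f"{mtx_path.name} declares {mat.shape[0]} rows"
        )
    if len(barcodes) != mat.shape[1]:
        raise FormatError(
            f"{bc_path.name} lists {len(barcodes)} barcodes but "
            f"{mtx_path.name} declares {mat.shape[1]} columns"
        )
    symbols = _deduplicate(symbols)
    return CountMatrix(mat, pd.Index(symbols), pd.Index(barcodes))


def write_10x_mtx(counts: CountMatrix, directory: str | os.PathLike) -> None:
    """Write a CountMatrix in the 10x plain-text layout (v3 three-column features)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(counts.values)
    # deterministic entry order: column-major like CellRanger
    order = np.lexsort((coo.row, coo.col))
    sorted_coo = sp.coo_matrix(
        (coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape
    )
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"), sorted_coo, field="integer", symmetry="general"
    )
    feats = pd.DataFrame(
        {
            "id": counts.gene_ids,
            "symbol": counts.gene_ids,
            "type": "Gene Expression",
        }
    )
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def _read_symbol_file(path: str | os.PathLike, what: str) -> list[str]:
    path = Path(path)
    with _open_maybe_gz(path) as fh:
        raw = [line.strip() for line in fh]
    symbols = [s for s in raw if s]
    if not symbols:
        raise FormatError(f"{what} file {path} is empty")
    unique = list(dict.fromkeys(symbols))
    n_dup = len(symbols) - len(unique)
    if n_dup:
        logger.warning("%s file %s: removed %d duplicated symbol(s)", what, path, n_dup)
    return unique


def read_gene_sets(path_s: str | os.PathLike, path_g2m: str | os.PathLike) -> GeneSetPair:
    """Read S-phase and G2/M gene lists (one symbol per line, whitespace-trimmed).

    Duplicates within a list are removed with a warning; a symbol present in
    both lists is an error because the permutation test requires disjoint sets.
    """
    s_genes = _read_symbol_file(path_s, "S gene set")
    g2m_genes = _read_symbol_file(path_g2m, "G2/M gene set")
    return GeneSetPair(s_genes, g2m_genes)


def read_tf_list(path: str | os.PathLike) -> TFList:
    """Read a transcription-factor symbol list (one per line)."""
    return TFList(frozenset(_read_symbol_file(path, "TF list")))
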