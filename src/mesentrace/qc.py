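"""Cell quality control, depth normalization, and covariate regression.

QC excludes presumed doublets and damaged cells: a cell is removed iff it
detects more than ``max_genes`` genes, fewer than ``min_genes`` genes, or
more than ``max_pct_mito`` percent of its UMIs map to mitochondrial genes
(identified by gene-name prefix). Boundary cells are retained: the
exclusion predicate is strict. Normalization scales each cell's depth to
``scale_total`` molecules and applies ln(1 + x). Covariate regression
removes, per gene, the OLS fit on total UMIs and mitochondrial percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

__all__ = ["CellQC", "NormalizedMatrix", "QCError", "qc_filter", "normalize_log", "regress_covariates"]


class QCError(ValueError):
    pass


@dataclass
class CellQC:
    """Per-cell QC statistics and pass flags for *all* input cells."""

    table: pd.DataFrame  # columns: cell_id, n_genes_detected, n_umi, pct_mito, pass_flag

    @property
    def pass_mask(self) -> np.ndarray:
        return self.table["pass_flag"].to_numpy()


@dataclass
class NormalizedMatrix:
    """Genes x cells expression on the natural-log scale.

    ``residualized`` marks whether per-gene covariate regression has been
    applied (residuals may then be negative).
    """

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    scale_total: float = 1e4
    residualized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match id lists")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def compute_cell_stats(counts: CountMatrix, mito_prefix: str = "mt-") -> pd.DataFrame:
    """n_genes_detected, n_umi and pct_mito (100 x mito UMIs / total UMIs) per cell."""
    csc = sp.csc_matrix(counts.values)
    n_umi = np.asarray(csc.sum(axis=0)).ravel()
    n_genes_detected = csc.getnnz(axis=0)
    mito_mask = counts.gene_ids.str.startswith(mito_prefix)
    mito_umi = np.asarray(csc[np.asarray(mito_mask)].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": counts.cell_ids,
            "n_genes_detected": n_genes_detected,
            "n_umi": n_umi.astype(int),
            "pct_mito": pct_mito,
        }
    )


def qc_filter(
    counts: CountMatrix,
    max_genes: int = 6000,
    min_genes: int = 200,
    max_pct_mito: float = 5.0,
    mito_prefix: str = "mt-",
) -> tuple[CountMatrix, CellQC]:
    """Remove doublets and poor-quality cells.

    A cell is excluded iff n_genes_detected > max_genes, n_genes_detected <
    min_genes, or pct_mito > max_pct_mito (strict inequalities; cells
    exactly at a threshold pass). The gene list is unchanged.
    """
    if max_genes <= 0 or min_genes <= 0 or max_pct_mito <= 0:
        raise QCError("QC thresholds must be positive")
    if min_genes > max_genes:
        raise QCError(f"min_genes ({min_genes}) exceeds max_genes ({max_genes})")
    stats = compute_cell_stats(counts, mito_prefix=mito_prefix)
    excluded = (
        (stats["n_genes_detected"] > max_genes)
        | (stats["n_genes_detected"] < min_genes)
        | (stats["pct_mito"] > max_pct_mito)
    )
    stats["pass_flag"] = ~excluded
    if not stats["pass_flag"].any():
        raise QCError("no cells survive QC; downstream stages are undefined")
    filtered = counts.subset_cells(stats["pass_flag"].to_numpy())
    return filtered, CellQC(stats)


def normalize_log(counts: CountMatrix, scale_total: float = 1e4) -> NormalizedMatrix:
    """Depth-normalize to ``scale_total`` molecules per cell, then ln(1 + x).

    entry = ln(1 + count * scale_total / cell_total); invariant to scaling
    all counts of a cell by a constant.
    """
    csc = sp.csc_matrix(counts.values, dtype=float)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        bad = counts.cell_ids[totals <= 0][:5].tolist()
        raise QCError(f"cells with zero total UMIs must be filtered first: {bad}")
    scaled = csc.multiply(scale_total / totals[None, :]).toarray()
    return NormalizedMatrix(
        np.log1p(scaled), counts.gene_ids, counts.cell_ids, scale_total=scale_total
    )


def regress_covariates(
    norm: NormalizedMatrix, covariates: pd.DataFrame | np.ndarray
) -> NormalizedMatrix:
    """Residualize each gene on intercept + covariates by ordinary least squares.

    Typical covariates are total UMIs and mitochondrial percentage.
    Constant or collinear covariate columns are dropped with a warning.
    Residuals are exactly orthogonal to the retained design columns.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != norm.n_cells:
        raise ValueError("covariates must have one row per cell")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if norm.n_cells < 3:
        raise ValueError("need at least 3 cells to regress covariates")

    design = np.column_stack([np.ones(norm.n_cells), X])
    # drop collinear columns, keeping the earliest of each dependent group
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        keep = [0]
        for j in range(1, design.shape[1]):
            trial = design[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        import warnings

        warnings.warn(
            f"dropping {design.shape[1] - len(keep)} collinear covariate column(s)",
            stacklevel=2,
        )
        design = design[:, keep]

    # residuals via least squares: Y - D (D^+ Y), vectorized over genes
    Y = norm.values.T  # cells x genes
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ coef
    return NormalizedMatrix(
        resid.T,
        norm.gene_ids,
        norm.cell_ids,
        scale_total=norm.scale_total,
        residualized=True,
    )
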