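"""Nonparametric permutation test classifying proliferative cells.

A cell is called proliferative when it expresses one cell-cycle gene set
(S-phase or G2/M) significantly more than the other. The null distribution
of the mean-expression difference between the two sets is unknown, so it
is built per cell by permuting the set labels: with n_S S genes and n_G
G2/M genes among the n_total = n_S + n_G retained cycle genes, each
resample redraws n_S of the n_total genes as pseudo-S and treats the rest
as pseudo-G2/M, recomputing the difference of mean expression. The
two-sided Monte-Carlo p-value uses the add-one estimator
(1 + #{|resample| >= |observed|}) / (B + 1); when the number of distinct
splits C(n_total, n_S) is small the test enumerates them all exactly
instead (p = #{|split| >= |observed|} / C, which is a valid exact p-value
because the observed split is itself among those enumerated). Multiple testing is corrected by Benjamini-Hochberg separately
within each cluster, and a cell is proliferative iff its FDR < alpha.

Before testing, cycle genes expressed in fewer than 5% of all cells are
removed (with a core set of 43 S and 54 G2/M genes and typical sparsity
this leaves a few dozen genes per set).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment
from .io import GeneSetPair
from .qc import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CycleGeneSets",
    "ProliferationCall",
    "filter_cycle_genes",
    "permutation_pvalue",
    "score_cells",
    "classify_proliferative",
    "proliferative_fraction",
]

EXHAUSTIVE_LIMIT = 100_000


@dataclass
class CycleGeneSets:
    """Cycle gene lists actually used by the test, after prevalence filtering."""

    s_used: list[str]
    g2m_used: list[str]
    dropped: list[str]

    @property
    def n_s(self) -> int:
        return len(self.s_used)

    @property
    def n_g2m(self) -> int:
        return len(self.g2m_used)

    @property
    def n_total(self) -> int:
        return self.n_s + self.n_g2m


@dataclass
class ProliferationCall:
    """Per-cell test results.

    Columns of ``table``: cell_id, cluster, observed_diff (mean S - mean
    G2/M on the log-normalized scale), p_value, fdr, proliferative,
    dominant_set ('S', 'G2M', or 'none').
    """

    table: pd.DataFrame


def filter_cycle_genes(
    norm: NormalizedMatrix, sets: GeneSetPair, min_prevalence: float = 0.05
) -> CycleGeneSets:
    """Drop cycle genes absent from the matrix or expressed in < min_prevalence of cells."""
    present = set(norm.gene_ids)
    dropped: list[str] = []

    def keep(symbols: list[str]) -> list[str]:
        kept = []
        for s in symbols:
            if s not in present:
                dropped.append(s)
                continue
            row = norm.values[norm.gene_ids.get_loc(s)]
            if (row > 0).mean() >= min_prevalence:
                kept.append(s)
            else:
                dropped.append(s)
        return kept

    s_used = keep(sets.s_genes)
    g2m_used = keep(sets.g2m_genes)
    if dropped:
        logger.info("prevalence filter removed %d cycle gene(s): %s", len(dropped), dropped)
    if not s_used or not g2m_used:
        raise ValueError(
            "a cycle gene set is empty after the prevalence filter; the test is undefined"
        )
    return CycleGeneSets(s_used, g2m_used, dropped)


def _perm_weights(n_total: int, n_s: int, B: int, seed: int, exhaustive: str):
    """Column-stacked contrast vectors: +1/n_S on pseudo-S genes, -1/n_G on the rest.

    Returns (weights, n_resamples, is_exhaustive). The same resample set is
    shared across all cells of a run for reproducibility.
    """
    n_g = n_total - n_s
    n_splits = math.comb(n_total, n_s)
    if exhaustive == "on" and n_splits > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"exhaustive enumeration requested but C({n_total},{n_s}) = {n_splits} "
            f"exceeds {EXHAUSTIVE_LIMIT}; use exhaustive='auto' or 'off'"
        )
    use_exhaustive = exhaustive == "on" or (exhaustive == "auto" and n_splits <= EXHAUSTIVE_LIMIT)
    if use_exhaustive:
        W = np.full((n_total, n_splits), -1.0 / n_g)
        for j, comb in enumerate(combinations(range(n_total), n_s)):
            W[list(comb), j] = 1.0 / n_s
        return W, n_splits, True
    rng = np.random.default_rng(seed)
    W = np.full((n_total, B), -1.0 / n_g)
    for j in range(B):
        idx = rng.choice(n_total, size=n_s, replace=False)
        W[idx, j] = 1.0 / n_s
    return W, B, False


def permutation_pvalue(
    cell_expression: np.ndarray,
    n_s: int,
    B: int = 5000,
    seed: int = 0,
    exhaustive: str = "auto",
) -> tuple[float, float]:
    """Permutation test for a single cell.

    ``cell_expression`` holds the cell's expression over the n_total cycle
    genes, S genes first. Returns (observed_diff, two-sided p-value).
    ``exhaustive``: 'auto' enumerates all C(n_total, n_s) splits when that
    count <= 1e5, 'on' forces enumeration, 'off' forces Monte-Carlo with B
    resamples and the add-one estimator.
    """
    x = np.asarray(cell_expression, dtype=float)
    n_total = x.size
    if n_s <= 0 or n_s >= n_total:
        raise ValueError(f"n_s must satisfy 0 < n_s < n_total; got n_s={n_s}, n_total={n_total}")
    if B < 1:
        raise ValueError("B must be >= 1")
    obs, p = score_cells(x[None, :], n_s, B=B, seed=seed, exhaustive=exhaustive)
    return float(obs[0]), float(p[0])


def score_cells(
    expression: np.ndarray,
    n_s: int,
    B: int = 5000,
    seed: int = 0,
    exhaustive: str = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized permutation test over many cells.

    ``expression`` is cells x n_total (cycle genes, S first). One resample
    index set is drawn once and shared by all cells. Returns
    (observed_diff, p_values) arrays.
    """
    X = np.atleast_2d(np.asarray(expression, dtype=float))
    n_total = X.shape[1]
    if n_s <= 0 or n_s >= n_total:
        raise ValueError(f"n_s must satisfy 0 < n_s < n_total; got n_s={n_s}, n_total={n_total}")
    n_g = n_total - n_s
    w_obs = np.concatenate([np.full(n_s, 1.0 / n_s), np.full(n_g, -1.0 / n_g)])
    obs = X @ w_obs

    W, n_resamples, is_exhaustive = _perm_weights(n_total, n_s, B, seed, exhaustive)
    null = X @ W  # cells x resamples
    eps = 1e-12  # tolerance so ties with the observed split count as extreme
    exceed = (np.abs(null) >= np.abs(obs)[:, None] - eps).sum(axis=1)
    if is_exhaustive:
        p = exceed / n_resamples  # exact: the observed split is among those enumerated
    else:
        p = (1.0 + exceed) / (n_resamples + 1.0)
    return obs, np.minimum(p, 1.0)


def classify_proliferative(
    observed_diff: np.ndarray,
    p_values: np.ndarray,
    clusters: ClusterAssignment,
    alpha: float = 0.05,
) -> ProliferationCall:
    """Benjamini-Hochberg within each cluster; proliferative iff FDR < alpha.

    The dominant set is S when the observed difference of a proliferative
    cell is positive, G2M when negative, and 'none' for non-proliferative
    cells.
    """
    labels = clusters.labels
    obs = np.asarray(observed_diff, dtype=float)
    pvals = np.asarray(p_values, dtype=float)
    if len(labels) != obs.size or obs.size != pvals.size:
        raise ValueError("observed_diff, p_values and cluster labels must align")
    fdr = np.full_like(pvals, np.nan)
    for cid in labels.unique():
        mask = (labels == cid).to_numpy()
        if mask.sum() == 0:
            logger.warning("cluster %s is empty; skipped", cid)
            continue
        fdr[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    proliferative = fdr < alpha
    dominant = np.where(proliferative, np.where(obs > 0, "S", "G2M"), "none")
    table = pd.DataFrame(
        {
            "cell_id": labels.index,
            "cluster": labels.to_numpy(),
            "observed_diff": obs,
            "p_value": pvals,
            "fdr": fdr,
            "proliferative": proliferative,
            "dominant_set": dominant,
        }
    )
    return ProliferationCall(table)


def proliferative_fraction(calls: ProliferationCall) -> pd.DataFrame:
    """Per-cluster proliferative counts and fractions (as in a cluster-wise bar plot)."""
    t = calls.table
    grouped = t.groupby("cluster")["proliferative"].agg(["sum", "size"])
    out = pd.DataFrame(
        {
            "cluster": grouped.index,
            "n_proliferative": grouped["sum"].astype(int),
            "n_cells": grouped["size"].astype(int),
        }
    ).reset_index(drop=True)
    out["fraction"] = out["n_proliferative"] / out["n_cells"]
    return out
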