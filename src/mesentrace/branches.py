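"""Branch-dependent expression testing and pseudotime trend classification.

The branch test asks, per gene, whether the expression trend along
pseudotime differs between the osteogenic and adipogenic branches. Counts
are modelled with a negative-binomial log-link GLM with a log library-size
offset; the full model gives each branch its own intercept and natural
cubic spline (df = 3) in pseudotime, the reduced model shares one spline
across branches, and the likelihood-ratio statistic is referred to a
chi-square with 4 degrees of freedom (branch intercept + 3 spline
contrasts). Per-gene NB dispersion is a method-of-moments estimate held
fixed during fitting; genes whose NB fit fails fall back to a Gaussian
model on log-normalized expression (logged). Lineage trends (up / down /
flat) come from the sign of an NB regression slope on pseudotime at a BH
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, TFList

logger = logging.getLogger(__name__)

__all__ = [
    "BranchTestResult",
    "LineageTrend",
    "natural_spline_basis",
    "branch_dependence_test",
    "lineage_trend",
    "filter_tfs",
    "heatmap_order",
]

BRANCH_TEST_DF = 4  # branch intercept + 3 branch-specific spline contrasts


@dataclass
class BranchTestResult:
    """Per-gene LRT results; columns: gene_id, lrt, df, p_value, p_adj, branch_dependent."""

    table: pd.DataFrame


@dataclass
class LineageTrend:
    """Per-gene trend within one lineage; columns: gene_id, slope, p_value, p_adj, direction."""

    table: pd.DataFrame
    lineage: str


def natural_spline_basis(
    x: np.ndarray, df: int = 3, knots: np.ndarray | None = None
) -> np.ndarray:
    """Natural cubic spline basis (no intercept column), df columns.

    Boundary knots at min/max of x, interior knots at equally spaced
    quantiles, as in the usual regression-spline construction. Linear
    beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        probs = np.linspace(0, 1, df + 1)
        knots = np.quantile(x, probs)
        knots = np.unique(knots)
    if len(knots) < 3:  # not enough distinct values: fall back to linear
        basis = np.column_stack([x] + [np.zeros_like(x)] * (df - 1))
        return basis
    K = len(knots)

    def d(j: int) -> np.ndarray:
        num = np.maximum(x - knots[j], 0) ** 3 - np.maximum(x - knots[K - 1], 0) ** 3
        return num / (knots[K - 1] - knots[j])

    cols = [x]
    dK2 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK2)
    basis = np.column_stack(cols)
    if basis.shape[1] < df:  # pad if duplicate knots collapsed the basis
        pad = np.zeros((len(x), df - basis.shape[1]))
        basis = np.column_stack([basis, pad])
    return basis[:, :df]


def _mom_dispersion(y: np.ndarray, offset_scale: np.ndarray) -> float:
    """Method-of-moments NB dispersion on depth-scaled counts, floored at 1e-8."""
    scaled = y / offset_scale
    m = scaled.mean()
    v = scaled.var(ddof=1)
    if m <= 0:
        return 1e-8
    return max((v - m) / m**2, 1e-8)


def _nb_llf(y, X, offset, alpha):
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset)
    res = model.fit(maxiter=100)
    if not np.isfinite(res.llf):
        raise ValueError("non-finite NB log-likelihood")
    return res


def _gaussian_lrt(y_log, X_full, X_red):
    """Gaussian fallback: LRT = n ln(RSS_red / RSS_full)."""
    n = len(y_log)
    rss_full = np.sum((y_log - X_full @ np.linalg.lstsq(X_full, y_log, rcond=None)[0]) ** 2)
    rss_red = np.sum((y_log - X_red @ np.linalg.lstsq(X_red, y_log, rcond=None)[0]) ** 2)
    rss_full = max(rss_full, 1e-300)
    return n * np.log(max(rss_red, 1e-300) / rss_full)


def branch_dependence_test(
    counts: CountMatrix,
    pseudotime: np.ndarray,
    branch: np.ndarray,
    genes: list[str] | None = None,
    alpha_flag: float = 0.05,
) -> BranchTestResult:
    """Likelihood-ratio test for branch-dependent pseudotime trends.

    Only cells on the two non-trunk branches enter the test; each branch
    must contribute >= 10 cells. ``branch`` holds per-cell branch ids
    ('trunk' cells are excluded). BH correction across genes; a gene is
    branch_dependent when its adjusted p < ``alpha_flag``.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    branch = np.asarray(branch, dtype=object)
    if not np.all(np.isfinite(pseudotime)):
        raise ValueError("pseudotime must be finite")
    ids = [b for b in pd.unique(branch) if b != "trunk"]
    if len(ids) != 2:
        raise ValueError(f"expected exactly 2 non-trunk branches, got {ids}")
    mask = np.isin(branch, ids)
    for b in ids:
        if (branch == b).sum() < 10:
            raise ValueError(f"branch {b!r} has fewer than 10 cells past the branch point")

    X = sp.csr_matrix(counts.values)[:, mask]
    pt = pseudotime[mask]
    is_b2 = (branch[mask] == ids[1]).astype(float)
    libsize = np.asarray(X.sum(axis=0)).ravel()
    offset = np.log(np.maximum(libsize, 1.0))

    spline = natural_spline_basis(pt, df=3)
    ones = np.ones(mask.sum())
    X_red = np.column_stack([ones, spline])
    X_full = np.column_stack([ones, is_b2, spline, spline * is_b2[:, None]])

    if genes is None:
        genes = list(counts.gene_ids)
    rows = []
    for g in genes:
        y = np.asarray(X[counts.gene_ids.get_loc(g)].todense()).ravel()
        if y.sum() == 0:
            rows.append((g, 0.0, BRANCH_TEST_DF, 1.0))
            continue
        phi = _mom_dispersion(y, np.exp(offset) / np.median(np.exp(offset)))
        try:
            full = _nb_llf(y, X_full, offset, phi)
            red = _nb_llf(y, X_red, offset, phi)
            lrt = max(2.0 * (full.llf - red.llf), 0.0)
        except Exception:
            logger.info("NB fit failed for %s; Gaussian fallback on log-normalized", g)
            y_log = np.log1p(y / np.exp(offset) * 1e4)
            lrt = max(_gaussian_lrt(y_log, X_full, X_red), 0.0)
        p = stats.chi2.sf(lrt, BRANCH_TEST_DF)
        rows.append((g, lrt, BRANCH_TEST_DF, p))
    table = pd.DataFrame(rows, columns=["gene_id", "lrt", "df", "p_value"])
    table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["branch_dependent"] = table["p_adj"] < alpha_flag
    return BranchTestResult(table)


def lineage_trend(
    counts: CountMatrix,
    pseudotime: np.ndarray,
    in_lineage: np.ndarray,
    genes: list[str] | None = None,
    lineage_id: str = "lineage",
    alpha_flag: float = 0.05,
) -> LineageTrend:
    """Up/down/flat pseudotime trend per gene within one lineage.

    NB regression of counts on pseudotime with a log library-size offset;
    direction = sign of the slope when BH-adjusted p < ``alpha_flag``,
    else 'flat'. Constant and all-zero genes are flat with p = 1.
    """
    in_lineage = np.asarray(in_lineage, dtype=bool)
    if in_lineage.sum() < 10:
        raise ValueError("lineage needs at least 10 cells")
    X = sp.csr_matrix(counts.values)[:, in_lineage]
    pt = np.asarray(pseudotime, dtype=float)[in_lineage]
    libsize = np.asarray(X.sum(axis=0)).ravel()
    offset = np.log(np.maximum(libsize, 1.0))
    design = np.column_stack([np.ones(in_lineage.sum()), pt])

    if genes is None:
        genes = list(counts.gene_ids)
    rows = []
    for g in genes:
        y = np.asarray(X[counts.gene_ids.get_loc(g)].todense()).ravel()
        if y.sum() == 0 or np.all(y == y[0]):
            rows.append((g, 0.0, 1.0))
            continue
        phi = _mom_dispersion(y, np.exp(offset) / np.median(np.exp(offset)))
        try:
            res = _nb_llf(y, design, offset, phi)
            slope = res.params[1]
            p = res.pvalues[1]
            if not np.isfinite(p):
                raise ValueError("non-finite Wald p")
        except Exception:
            logger.info("NB trend fit failed for %s; Gaussian fallback", g)
            y_log = np.log1p(y / np.exp(offset) * 1e4)
            lr = stats.linregress(pt, y_log)
            slope, p = lr.slope, lr.pvalue
        rows.append((g, float(slope), float(p)))
    table = pd.DataFrame(rows, columns=["gene_id", "slope", "p_value"])
    table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
    table["direction"] = np.where(
        table["p_adj"] < alpha_flag, np.where(table["slope"] > 0, "up", "down"), "flat"
    )
    return LineageTrend(table, lineage=lineage_id)


def filter_tfs(table: pd.DataFrame, tfs: TFList, gene_col: str = "gene_id") -> pd.DataFrame:
    """Rows whose gene symbol is a transcription factor, input order preserved."""
    mask = table[gene_col].isin(tfs.symbols)
    return table.loc[mask].reset_index(drop=True)


def heatmap_order(
    expression: np.ndarray,
    gene_ids: pd.Index,
    pseudotime: np.ndarray,
    branch: np.ndarray,
    genes: list[str],
    branch_left: str | None = None,
    n_bins: int = 20,
    smooth_window: int = 3,
) -> pd.DataFrame:
    """Bin, smooth, and order genes for a branched pseudotime heatmap.

    Cells of the two non-trunk branches are binned along pseudotime per
    branch; columns run from the left branch's terminus inward to the
    branch point (center) and outward to the right branch's terminus.
    Rows are smoothed with a rolling mean over bins, grouped by the branch
    in which they peak (left-branch peakers first), and ordered within a
    group by peak position. Returns a genes x bins DataFrame with a
    'group' column.
    """
    gene_ids = pd.Index(gene_ids)
    branch = np.asarray(branch, dtype=object)
    pt = np.asarray(pseudotime, dtype=float)
    ids = [b for b in pd.unique(branch) if b != "trunk"]
    if len(ids) != 2:
        raise ValueError(f"expected exactly 2 non-trunk branches, got {ids}")
    if branch_left is None:
        branch_left = sorted(ids)[0]
    branch_right = ids[0] if ids[1] == branch_left else ids[1]

    def branch_bins(bid: str) -> np.ndarray:
        mask = branch == bid
        bpt = pt[mask]
        sub = expression[np.ix_(gene_ids.get_indexer(genes), np.where(mask)[0])]
        edges = np.linspace(bpt.min(), bpt.max(), n_bins + 1)
        which = np.clip(np.digitize(bpt, edges[1:-1]), 0, n_bins - 1)
        out = np.zeros((len(genes), n_bins))
        for b in range(n_bins):
            sel = which == b
            out[:, b] = sub[:, sel].mean(axis=1) if sel.any() else np.nan
        # forward/backward fill empty bins so smoothing stays defined
        df = pd.DataFrame(out).ffill(axis=1).bfill(axis=1)
        return df.to_numpy()

    def smooth(block: np.ndarray) -> np.ndarray:
        w = min(smooth_window, block.shape[1])
        return pd.DataFrame(block.T).rolling(w, min_periods=1, center=True).mean().T.to_numpy()

    # smooth within each branch so the rolling mean never crosses the fork
    left = smooth(branch_bins(branch_left))[:, ::-1]  # terminus -> branch point
    right = smooth(branch_bins(branch_right))  # branch point -> terminus
    smoothed = np.hstack([left, right])

    peak = smoothed.argmax(axis=1)
    group = np.where(peak < n_bins, branch_left, branch_right)
    names = np.asarray(genes, dtype=object)
    order = np.lexsort((names, peak, group != branch_left))  # left-branch group first
    cols = [f"{branch_left}_bin{n_bins - i}" for i in range(n_bins)] + [
        f"{branch_right}_bin{i + 1}" for i in range(n_bins)
    ]
    out = pd.DataFrame(smoothed[order], index=np.asarray(genes)[order], columns=cols)
    out.insert(0, "group", group[order])
    return out
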