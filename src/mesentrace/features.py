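"""Per-gene dispersion, mean-dispersion trend, and ordering-gene selection.

Genes that drive the trajectory are picked by the rule
``mean_expression >= 0.05 and dispersion_empirical >= 2 * dispersion_fit``:
mean and overdispersion are computed on depth-scaled counts (each cell
scaled to the median library size), the empirical NB dispersion is the
method-of-moments estimate phi = (var - mean) / mean^2, and the expected
dispersion at a given mean comes from a fitted a + b / mu trend (gamma
regression across genes). Highly variable genes for dimensionality
reduction are instead the top-k by dispersion ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm

from .io import CountMatrix

__all__ = [
    "DispersionTable",
    "estimate_dispersion",
    "fit_dispersion_trend",
    "select_ordering_genes",
    "select_top_dispersion",
]


@dataclass
class DispersionTable:
    """Per-gene dispersion summary.

    Columns of ``table``: gene_id, mean_expression, dispersion_empirical,
    dispersion_fit (NaN until the trend is fitted), ordering_flag.
    ``trend_coef`` holds (a, b) of the fitted a + b/mu curve.
    """

    table: pd.DataFrame
    trend_coef: tuple | None = None


def estimate_dispersion(counts: CountMatrix) -> DispersionTable:
    """Method-of-moments NB dispersion on depth-scaled counts.

    Counts are scaled per cell to the median library size (size-factor
    normalization); per gene, phi = max(0, (var - mean) / mean^2), so a
    Poisson-like gene gets phi ~ 0 and a constant gene gets exactly 0.
    """
    if counts.n_cells < 2:
        raise ValueError("dispersion estimation needs at least 2 cells")
    csc = sp.csc_matrix(counts.values, dtype=float)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts must be filtered first")
    size_factors = totals / np.median(totals)
    scaled = csc.multiply(1.0 / size_factors[None, :]).tocsr()

    n = counts.n_cells
    mean = np.asarray(scaled.mean(axis=1)).ravel()
    sq = scaled.copy()
    sq.data **= 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(mean > 0, (var - mean) / mean**2, 0.0)
    phi = np.maximum(phi, 0.0)

    table = pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "mean_expression": mean,
            "dispersion_empirical": phi,
            "dispersion_fit": np.nan,
            "ordering_flag": False,
        }
    )
    return DispersionTable(table)


def fit_dispersion_trend(disp: DispersionTable) -> DispersionTable:
    """Fit dispersion_fit(mu) = a + b / mu across genes by gamma regression.

    Only genes with positive mean and positive empirical dispersion inform
    the fit; the fitted curve is evaluated (and floored at a tiny positive
    value) for every gene with positive mean.
    """
    t = disp.table
    use = (t["mean_expression"] > 0) & (t["dispersion_empirical"] > 0)
    if use.sum() < 10:
        raise ValueError(
            f"trend fit needs >= 10 genes with positive mean and dispersion, got {int(use.sum())}"
        )
    mu = t.loc[use, "mean_expression"].to_numpy()
    phi = t.loc[use, "dispersion_empirical"].to_numpy()
    X = np.column_stack([np.ones_like(mu), 1.0 / mu])
    try:
        import warnings

        with warnings.catch_warnings():
            # identity link on the Gamma family is intentional (Monocle-style
            # a + b/mu trend); statsmodels warns about the unusual pairing
            warnings.simplefilter("ignore")
            model = sm.GLM(phi, X, family=sm.families.Gamma(link=sm.families.links.Identity()))
            res = model.fit(start_params=np.array([np.median(phi), 1e-3]), maxiter=200)
        a, b = res.params
        if not np.all(np.isfinite([a, b])):
            raise ValueError("non-finite gamma-fit coefficients")
    except Exception:
        # fall back to least squares on the same curve
        coef, *_ = np.linalg.lstsq(X, phi, rcond=None)
        a, b = coef

    out = t.copy()
    mean_all = out["mean_expression"].to_numpy()
    with np.errstate(divide="ignore"):
        fitted = a + b / np.where(mean_all > 0, mean_all, np.nan)
    floor = 1e-8
    out["dispersion_fit"] = np.where(np.isnan(fitted), np.nan, np.maximum(fitted, floor))
    return DispersionTable(out, trend_coef=(float(a), float(b)))


def _require_fitted(disp: DispersionTable) -> pd.DataFrame:
    if disp.table["dispersion_fit"].isna().all():
        raise ValueError("dispersion trend has not been fitted")
    return disp.table


def select_ordering_genes(
    disp: DispersionTable, min_mean: float = 0.05, fold: float = 2.0
) -> list[str]:
    """Genes with mean_expression >= min_mean and empirical >= fold x fitted dispersion.

    Both comparisons are inclusive (a gene exactly on either boundary is
    selected). Returns gene ids in the table's order; an empty result is a
    warning, not an error.
    """
    t = _require_fitted(disp)
    flag = (
        (t["mean_expression"] >= min_mean)
        & t["dispersion_fit"].notna()
        & (t["dispersion_empirical"] >= fold * t["dispersion_fit"])
    )
    disp.table["ordering_flag"] = flag.to_numpy()
    selected = t.loc[flag.to_numpy(), "gene_id"].tolist()
    if not selected:
        import warnings

        warnings.warn("ordering-gene rule selected no genes", stacklevel=2)
    return selected


def select_top_dispersion(disp: DispersionTable, k: int = 2000) -> list[str]:
    """Top-k genes by dispersion ratio (empirical / fitted), ties by gene id.

    The ratio, rather than raw dispersion, removes the mean-dispersion
    trend so selection is not mean-driven.
    """
    t = _require_fitted(disp)
    if k > len(t):
        raise ValueError(f"k = {k} exceeds the number of genes ({len(t)})")
    ratio = t["dispersion_empirical"] / t["dispersion_fit"]
    ratio = ratio.fillna(-np.inf)
    order = sorted(range(len(t)), key=lambda i: (-ratio.iloc[i], t["gene_id"].iloc[i]))
    return t["gene_id"].iloc[order[:k]].tolist()
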