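import numpy as np
import pandas as pd
import pytest

import mesentrace as mt


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-lineage dataset for fast unit tests."""
    params = mt.SimParams(n_cells_per_population=80, n_genes=500, seed=42)
    counts, truth = mt.simulate_dataset(params)
    return params, counts, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default study-condition fixture: 6 populations x 500 cells, 2000 genes."""
    params = mt.SimParams(seed=11)
    counts, truth = mt.simulate_dataset(params)
    return params, counts, truth


@pytest.fixture(scope="session")
def default_processed(default_sim):
    """QC'd, normalized, residualized view of the default fixture plus PCs."""
    _, counts, truth = default_sim
    counts_f, cellqc = mt.qc.qc_filter(counts)
    norm = mt.qc.normalize_log(counts_f)
    stats = mt.qc.compute_cell_stats(counts_f)
    resid = mt.qc.regress_covariates(norm, stats[["n_umi", "pct_mito"]])
    disp = mt.features.fit_dispersion_trend(mt.features.estimate_dispersion(counts_f))
    hvg = mt.features.select_top_dispersion(disp, k=min(2000, counts_f.n_genes))
    pcs = mt.cluster.pca(resid, genes=hvg, n_pcs=30)
    tc = truth.cells.set_index("cell_id").loc[norm.cell_ids]
    return {
        "counts": counts_f,
        "norm": norm,
        "resid": resid,
        "disp": disp,
        "pcs": pcs,
        "truth_cells": tc,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def population_clusters(default_processed):
    """Planted populations encoded as a ClusterAssignment (EMP is cluster 0)."""
    tc = default_processed["truth_cells"]
    pops = ["EMP", "LMP", "LCP", "OB", "Ocy", "AD"]
    code = {p: i for i, p in enumerate(pops)}
    labels = pd.Series(
        [code[p] for p in tc["population"]], index=tc.index, name="cluster"
    )
    return mt.cluster.ClusterAssignment(labels), code
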