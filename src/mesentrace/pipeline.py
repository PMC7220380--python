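"""End-to-end orchestration: one config object, eight stages, one report.

``run_all`` executes read/simulate -> QC -> normalize -> feature selection
-> clustering -> cell-cycle permutation test -> trajectory -> branch
analysis, writing each stage's table under the output directory plus a
machine-readable JSON report (parameters, seed, per-stage row counts).
Reruns with an identical config and seed reproduce all outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import branches as br
from . import cellcycle as cc
from . import cluster as cl
from . import features as fs
from . import qc as qcmod
from . import trajectory as tj
from .io import GeneSetPair, read_10x_mtx, read_gene_sets, read_tf_list
from .simulate import SimParams, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_all"]

STAGES = ["input", "qc", "normalize", "features", "cluster", "cellcycle", "trajectory", "branches"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """All stage parameters with their conventional defaults.

    ``input_dir`` may be None, in which case a synthetic dataset is
    generated from ``sim_params`` (seeded by ``seed``). Gene-set paths
    default to the fixture's planted lists when present.
    """

    out_dir: str = "mesentrace_out"
    input_dir: str | None = None
    s_genes_path: str | None = None
    g2m_genes_path: str | None = None
    tf_list_path: str | None = None
    max_genes: int = 6000
    min_genes: int = 200
    max_pct_mito: float = 5.0
    mito_prefix: str = "mt-"
    scale_total: float = 1e4
    n_top_genes: int = 2000
    ordering_min_mean: float = 0.05
    ordering_fold: float = 2.0
    n_pcs: int = 30
    k_neighbors: int = 20
    resolution: float = 1.0
    n_perm: int = 5000
    alpha: float = 0.05
    root_cluster: int | None = None
    branch_test_gene_set: str = "ordering"  # or "all"
    seed: int = 0
    sim_params: SimParams | None = None


def validate_config(config: RunConfig) -> list[str]:
    """Return every violation found (empty list means the config is valid)."""
    errors = []
    for name in ("max_genes", "min_genes", "n_top_genes", "n_pcs", "k_neighbors", "n_perm"):
        v = getattr(config, name)
        if not isinstance(v, (int, np.integer)) or v <= 0:
            errors.append(f"{name} must be a positive integer, got {v!r}")
    for name in ("max_pct_mito", "scale_total", "ordering_min_mean", "ordering_fold",
                 "resolution", "alpha"):
        v = getattr(config, name)
        if not (isinstance(v, (int, float)) and v > 0):
            errors.append(f"{name} must be positive, got {v!r}")
    if isinstance(config.min_genes, int) and isinstance(config.max_genes, int):
        if config.min_genes > config.max_genes:
            errors.append(
                f"min_genes ({config.min_genes}) must not exceed max_genes ({config.max_genes})"
            )
    if config.branch_test_gene_set not in ("ordering", "all"):
        errors.append(f"branch_test_gene_set must be 'ordering' or 'all', got {config.branch_test_gene_set!r}")
    if config.input_dir is not None and not Path(config.input_dir).exists():
        errors.append(f"input_dir does not exist: {config.input_dir}")
    for name in ("s_genes_path", "g2m_genes_path", "tf_list_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            errors.append(f"{name} does not exist: {p}")
    return errors


def _resolve_gene_sets(config: RunConfig, fixture_truth) -> GeneSetPair:
    if config.s_genes_path and config.g2m_genes_path:
        return read_gene_sets(config.s_genes_path, config.g2m_genes_path)
    if config.input_dir is not None:
        d = Path(config.input_dir)
        s, g = d / "s_genes.txt", d / "g2m_genes.txt"
        if s.exists() and g.exists():
            return read_gene_sets(s, g)
    if fixture_truth is not None:
        return GeneSetPair(fixture_truth.s_genes, fixture_truth.g2m_genes)
    raise PipelineError("cellcycle: no S / G2M gene-set files available")


def _auto_root(tree: tj.LineageTree, prolif: pd.DataFrame) -> int:
    """Pick the MST leaf with the highest proliferative fraction as root.

    Progenitor pools cycle; terminally differentiated leaves do not, so
    among leaf clusters the most proliferative one is the best root guess
    when the user does not designate a progenitor cluster.
    """
    g = tree.graph()
    leaves = sorted(n for n in g.nodes if g.degree(n) == 1)
    frac = prolif.set_index("cluster")["fraction"]
    return int(max(leaves, key=lambda c: (frac.get(c, 0.0), -c)))


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON)."""
    errors = validate_config(config)
    if errors:
        raise PipelineError("config validation failed: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "sim_params"
        },
        "stages": {},
    }
    t_start = time.time()

    def record(stage: str, **counts) -> None:
        report["stages"][stage] = {"elapsed_s": round(time.time() - t_start, 2), **counts}
        logger.info("stage %s done: %s", stage, counts)

    truth = None
    try:
        # --- input -----------------------------------------------------
        if config.input_dir is not None:
            counts = read_10x_mtx(config.input_dir)
        else:
            params = config.sim_params or SimParams(seed=config.seed)
            counts, truth = simulate_dataset(params)
        record("input", n_genes=counts.n_genes, n_cells=counts.n_cells)

        # --- qc ---------------------------------------------------------
        counts, cellqc = qcmod.qc_filter(
            counts,
            max_genes=config.max_genes,
            min_genes=config.min_genes,
            max_pct_mito=config.max_pct_mito,
            mito_prefix=config.mito_prefix,
        )
        cellqc.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        record("qc", n_cells_pass=counts.n_cells, n_cells_fail=int((~cellqc.pass_mask).sum()))

        # --- normalize ---------------------------------------------------
        norm = qcmod.normalize_log(counts, scale_total=config.scale_total)
        covars = qcmod.compute_cell_stats(counts, mito_prefix=config.mito_prefix)
        resid = qcmod.regress_covariates(norm, covars[["n_umi", "pct_mito"]])
        record("normalize", n_cells=norm.n_cells)

        # --- features ----------------------------------------------------
        disp = fs.fit_dispersion_trend(fs.estimate_dispersion(counts))
        ordering_genes = fs.select_ordering_genes(
            disp, min_mean=config.ordering_min_mean, fold=config.ordering_fold
        )
        hvg = fs.select_top_dispersion(disp, k=min(config.n_top_genes, counts.n_genes))
        disp.table.to_csv(out / "dispersion_table.tsv", sep="\t", index=False)
        record("features", n_ordering_genes=len(ordering_genes), n_hvg=len(hvg))

        # --- cluster ------------------------------------------------------
        pcs = cl.pca(resid, genes=hvg, n_pcs=min(config.n_pcs, len(hvg) - 1, norm.n_cells - 1))
        clusters = cl.cluster_cells(
            pcs,
            cell_ids=norm.cell_ids,
            k_neighbors=config.k_neighbors,
            resolution=config.resolution,
            seed=config.seed,
        )
        clusters.labels.rename_axis("cell_id").to_frame().to_csv(out / "clusters.tsv", sep="\t")
        markers = []
        for cid in clusters.cluster_ids:
            if (clusters.labels == cid).sum() >= 3:
                mt = cl.find_markers(norm, clusters, cid)
                top = mt.table.head(20).copy()
                top.insert(0, "cluster", cid)
                markers.append(top)
        pd.concat(markers).to_csv(out / "markers.tsv", sep="\t", index=False)
        record("cluster", n_clusters=len(clusters.cluster_ids))

        # --- cellcycle ----------------------------------------------------
        sets = _resolve_gene_sets(config, truth)
        used = cc.filter_cycle_genes(norm, sets)
        idx = norm.gene_ids.get_indexer(used.s_used + used.g2m_used)
        expr = norm.values[idx, :].T  # cells x cycle genes
        obs, pvals = cc.score_cells(expr, used.n_s, B=config.n_perm, seed=config.seed)
        calls = cc.classify_proliferative(obs, pvals, clusters, alpha=config.alpha)
        prolif = cc.proliferative_fraction(calls)
        calls.table.to_csv(out / "cellcycle_calls.tsv", sep="\t", index=False)
        prolif.to_csv(out / "cluster_proliferation.tsv", sep="\t", index=False)
        record(
            "cellcycle",
            n_s_used=used.n_s,
            n_g2m_used=used.n_g2m,
            n_proliferative=int(calls.table["proliferative"].sum()),
        )

        # --- trajectory ----------------------------------------------------
        tree = tj.build_mst(pcs, clusters)
        root = config.root_cluster if config.root_cluster is not None else _auto_root(tree, prolif)
        tree = tj.extract_lineages(tree, root)
        ptime = tj.assign_pseudotime(pcs, clusters, tree)
        ptime.table.to_csv(out / "pseudotime.tsv", sep="\t", index=False)
        record(
            "trajectory",
            root_cluster=root,
            n_lineages=len(tree.lineages),
            branch_points=tree.branch_points,
        )

        # --- branches --------------------------------------------------------
        branch_ids = ptime.table.set_index("cell_id").loc[norm.cell_ids, "branch"].to_numpy()
        pt = ptime.table.set_index("cell_id").loc[norm.cell_ids, "pseudotime"].to_numpy()
        non_trunk = [b for b in pd.unique(branch_ids) if b != "trunk"]
        if len(non_trunk) > 2:
            # over-forked tree: keep the two most populated branches for the test
            keep = (
                pd.Series(branch_ids)[pd.Series(branch_ids) != "trunk"]
                .value_counts()
                .index[:2]
                .tolist()
            )
            branch_ids = np.where(np.isin(branch_ids, keep + ["trunk"]), branch_ids, "trunk")
        test_genes = ordering_genes if config.branch_test_gene_set == "ordering" else None
        bt = br.branch_dependence_test(counts, pt, branch_ids, genes=test_genes, alpha_flag=config.alpha)
        bt.table.to_csv(out / "branch_test.tsv", sep="\t", index=False)
        if config.tf_list_path:
            tfs = read_tf_list(config.tf_list_path)
            br.filter_tfs(bt.table, tfs).to_csv(out / "branch_test_tfs.tsv", sep="\t", index=False)
        trends = []
        for lid in pd.unique(branch_ids):
            if lid == "trunk":
                continue
            mask = (branch_ids == lid) | (branch_ids == "trunk")
            tr = br.lineage_trend(counts, pt, mask, genes=test_genes, lineage_id=str(lid),
                                  alpha_flag=config.alpha)
            t = tr.table.copy()
            t.insert(0, "lineage", lid)
            trends.append(t)
        pd.concat(trends).to_csv(out / "lineage_trends.tsv", sep="\t", index=False)
        sig = bt.table.loc[bt.table["branch_dependent"]].sort_values("p_adj")
        if len(sig):
            hm = br.heatmap_order(
                norm.values,
                norm.gene_ids,
                pt,
                branch_ids,
                sig["gene_id"].head(50).tolist(),
            )
            hm.to_csv(out / "heatmap_matrix.tsv", sep="\t")
        record(
            "branches",
            n_tested=len(bt.table),
            n_branch_dependent=int(bt.table["branch_dependent"].sum()),
        )
    except PipelineError:
        raise
    except Exception as exc:
        failed = next((s for s in STAGES if s not in report["stages"]), "unknown")
        raise PipelineError(f"stage {failed!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
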