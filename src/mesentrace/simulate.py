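"""Synthetic scRNA-seq generator with a planted bifurcating mesenchymal lineage.

The generator emulates the statistical structure a bone-marrow
mesenchymal-lineage dataset presents to the analysis pipeline: six
populations (early/late mesenchymal progenitors, a lineage-committed
progenitor at the branch point, osteoblasts and osteocytes on one branch,
adipocytes on the other) arranged on a Y-shaped differentiation topology;
negative-binomial UMI counts with log-normal library sizes; population
marker programs; branch-specific gene programs that diverge after the
branch point; S-phase and G2/M cycle modules up-shifted in a cycling
subpopulation; and mitochondrial genes (``mt-`` prefix) for QC.

Every planted quantity (population, pseudotime, branch, cycling flag and
phase, per-gene program) is returned as ground truth so downstream stages
can be scored against it.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, write_10x_mtx

__all__ = ["SimParams", "SimTruth", "SimConfigError", "simulate_dataset", "write_fixture"]


class SimConfigError(ValueError):
    """Raised when simulation parameters violate a topology or range invariant."""


def _default_cycling() -> dict:
    # progenitors cycle, terminally differentiated osteocytes/adipocytes do not
    return {"EMP": 0.20, "LMP": 0.15, "LCP": 0.10, "OB": 0.05, "Ocy": 0.0, "AD": 0.0}


@dataclass
class SimParams:
    """Parameters of the bifurcating-lineage count simulator.

    The topology is a Y: ``trunk`` runs from the root population to the
    branch point (its last element), then ``branch_osteo`` and
    ``branch_adipo`` each continue to a terminus. Defaults emulate a young
    endosteal bone-marrow mesenchymal dataset at desk scale: 6 populations,
    2,000 genes, ~5,000 UMIs/cell, moderate UMI overdispersion, 2-fold
    branch divergence at the termini, and cycling confined to progenitors.
    """

    n_cells_per_population: int = 500
    trunk: tuple = ("EMP", "LMP", "LCP")
    branch_osteo: tuple = ("OB", "Ocy")
    branch_adipo: tuple = ("AD",)
    n_genes: int = 2000
    n_marker_genes_per_population: int = 25
    n_branch_genes_per_branch: int = 40
    branch_log_fold: float = math.log(2.0)
    marker_log_fold: float = 2.0
    libsize_lognormal_mu_sigma: tuple = (math.log(5000.0), 0.35)
    nb_dispersion: float = 0.2
    frac_mito_genes: float = 0.01
    cycling_fraction_per_population: dict = field(default_factory=_default_cycling)
    cycle_effect_delta: float = 1.0
    n_s_genes: int = 43
    n_g2m_genes: int = 54
    seed: int = 0

    @property
    def populations(self) -> list[str]:
        return list(self.trunk) + list(self.branch_osteo) + list(self.branch_adipo)

    def validate(self) -> None:
        if len(self.trunk) < 1:
            raise SimConfigError("topology must have exactly one root: trunk is empty")
        if len(self.branch_osteo) < 1 or len(self.branch_adipo) < 1:
            raise SimConfigError(
                "topology must have exactly two termini: each branch needs >= 1 population"
            )
        pops = self.populations
        if len(set(pops)) != len(pops):
            raise SimConfigError("population names must be unique across the topology")
        for name, value in [
            ("n_cells_per_population", self.n_cells_per_population),
            ("n_genes", self.n_genes),
            ("n_s_genes", self.n_s_genes),
            ("n_g2m_genes", self.n_g2m_genes),
        ]:
            if int(value) <= 0:
                raise SimConfigError(f"{name} must be a positive integer, got {value}")
        if self.n_marker_genes_per_population < 0 or self.n_branch_genes_per_branch < 0:
            raise SimConfigError("gene-program counts must be non-negative integers")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        if not (0.0 <= self.frac_mito_genes <= 1.0):
            raise SimConfigError("frac_mito_genes must lie in [0, 1]")
        for pop, frac in self.cycling_fraction_per_population.items():
            if not (0.0 <= frac <= 1.0):
                raise SimConfigError(
                    f"cycling fraction for {pop!r} must lie in [0, 1], got {frac}"
                )
            if pop not in pops:
                raise SimConfigError(f"cycling fraction given for unknown population {pop!r}")
        if self.cycle_effect_delta < 0:
            raise SimConfigError("cycle_effect_delta must be positive")
        n_program = (
            len(pops) * self.n_marker_genes_per_population
            + 2 * self.n_branch_genes_per_branch
            + self.n_s_genes
            + self.n_g2m_genes
            + int(round(self.frac_mito_genes * self.n_genes))
        )
        if n_program > self.n_genes:
            raise SimConfigError(
                f"gene programs require {n_program} genes but n_genes = {self.n_genes}"
            )


@dataclass
class SimTruth:
    """Planted ground truth for a simulated dataset.

    ``cells`` has one row per cell: population, pseudotime (0 at the root
    start, arc position along the lineage), branch (trunk/osteo/adipo),
    cycling flag and phase. ``genes`` has one row per gene: program
    (marker / branch-osteo / branch-adipo / cycle-S / cycle-G2M / mito /
    background) and base log-mean. ``expected_counts`` is the dense matrix
    of per-cell NB means the counts were drawn from.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    expected_counts: np.ndarray
    params: SimParams

    @property
    def s_genes(self) -> list[str]:
        return self.genes.loc[self.genes["program"] == "cycle-S", "gene_id"].tolist()

    @property
    def g2m_genes(self) -> list[str]:
        return self.genes.loc[self.genes["program"] == "cycle-G2M", "gene_id"].tolist()


def _population_layout(params: SimParams) -> dict[str, dict]:
    """Anchor positions along each lineage: population i spans [i, i+1]."""
    layout = {}
    for i, pop in enumerate(params.trunk):
        layout[pop] = {"start": float(i), "branch": "trunk"}
    n_trunk = len(params.trunk)
    for i, pop in enumerate(params.branch_osteo):
        layout[pop] = {"start": float(n_trunk + i), "branch": "osteo"}
    for i, pop in enumerate(params.branch_adipo):
        layout[pop] = {"start": float(n_trunk + i), "branch": "adipo"}
    return layout


def simulate_dataset(params: SimParams) -> tuple[CountMatrix, SimTruth]:
    """Draw a count matrix with planted lineage / cycle structure.

    Counts are NB(mean, dispersion) with mean = library-size-scaled program
    mean; the program mean is piecewise-linear in log-space between
    population anchors along each cell's lineage. Identical params + seed
    give identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    pops = params.populations
    layout = _population_layout(params)
    n_pops = len(pops)
    n_cells = params.n_cells_per_population * n_pops
    n_genes = params.n_genes
    n_mito = int(round(params.frac_mito_genes * n_genes))

    # --- gene program bookkeeping -------------------------------------
    program = np.array(["background"] * n_genes, dtype=object)
    cursor = 0
    marker_of: dict[str, np.ndarray] = {}
    for pop in pops:
        idx = np.arange(cursor, cursor + params.n_marker_genes_per_population)
        marker_of[pop] = idx
        program[idx] = f"marker-{pop}"
        cursor = idx[-1] + 1 if len(idx) else cursor
    osteo_idx = np.arange(cursor, cursor + params.n_branch_genes_per_branch)
    program[osteo_idx] = "branch-osteo"
    cursor += params.n_branch_genes_per_branch
    adipo_idx = np.arange(cursor, cursor + params.n_branch_genes_per_branch)
    program[adipo_idx] = "branch-adipo"
    cursor += params.n_branch_genes_per_branch
    s_idx = np.arange(cursor, cursor + params.n_s_genes)
    program[s_idx] = "cycle-S"
    cursor += params.n_s_genes
    g2m_idx = np.arange(cursor, cursor + params.n_g2m_genes)
    program[g2m_idx] = "cycle-G2M"
    cursor += params.n_g2m_genes
    mito_idx = np.arange(cursor, cursor + n_mito)
    program[mito_idx] = "mito"
    cursor += n_mito

    gene_ids = np.array([f"Gene{i + 1:05d}" for i in range(n_genes)], dtype=object)
    gene_ids[mito_idx] = [f"mt-Gene{i + 1:05d}" for i in mito_idx]

    # base log-mean of relative expression; moderately expressed programs so
    # markers/branch/cycle genes clear detection and the 5% prevalence filter
    base_log = rng.normal(loc=-1.0, scale=1.5, size=n_genes)
    base_log[s_idx] = rng.normal(0.0, 0.3, size=len(s_idx))
    base_log[g2m_idx] = rng.normal(0.0, 0.3, size=len(g2m_idx))
    base_log[mito_idx] = rng.normal(1.5, 0.3, size=n_mito)
    for pop in pops:
        base_log[marker_of[pop]] = rng.normal(0.0, 0.5, size=len(marker_of[pop]))
    base_log[osteo_idx] = rng.normal(0.0, 0.5, size=len(osteo_idx))
    base_log[adipo_idx] = rng.normal(0.0, 0.5, size=len(adipo_idx))

    # --- per-cell truth ------------------------------------------------
    population = np.repeat(pops, params.n_cells_per_population)
    start = np.array([layout[p]["start"] for p in population])
    frac = rng.uniform(0.0, 1.0, size=n_cells)
    pseudotime = start + frac
    branch = np.array([layout[p]["branch"] for p in population], dtype=object)

    cycling = np.zeros(n_cells, dtype=bool)
    phase = np.array([""] * n_cells, dtype=object)
    for pop in pops:
        p_cyc = params.cycling_fraction_per_population.get(pop, 0.0)
        pop_mask = population == pop
        draws = rng.uniform(size=pop_mask.sum()) < p_cyc
        cycling[pop_mask] = draws
    n_cycling = int(cycling.sum())
    phases = np.where(rng.uniform(size=n_cycling) < 0.5, "S", "G2M")
    phase[cycling] = phases

    # --- mean curves: piecewise-linear in log-space --------------------
    # Each population has an anchor log-mean profile placed at the center
    # of its pseudotime interval; a cell's log-mean interpolates linearly
    # between the two anchors flanking its pseudotime along its lineage,
    # so expression varies continuously along each differentiation path.
    centers = {pop: layout[pop]["start"] + 0.5 for pop in pops}
    anchors = np.tile(base_log[:, None], (1, n_pops))  # genes x populations
    pop_col = {pop: j for j, pop in enumerate(pops)}
    for pop in pops:
        anchors[marker_of[pop], pop_col[pop]] += params.marker_log_fold
    # branch genes ramp from 0 at the branch-point center to the full
    # configured log-fold at the terminus center of their own branch
    fork_pop = params.trunk[-1]
    c_fork = centers[fork_pop]
    for branch_pops, gene_idx in [
        (params.branch_osteo, osteo_idx),
        (params.branch_adipo, adipo_idx),
    ]:
        c_term = centers[branch_pops[-1]]
        for pop in branch_pops:
            frac_ramp = (centers[pop] - c_fork) / (c_term - c_fork) if c_term > c_fork else 1.0
            anchors[gene_idx, pop_col[pop]] += params.branch_log_fold * frac_ramp

    # anchor paths: trunk cells past the fork head toward the average of
    # the two branch-head profiles; branch cells follow their own path
    def _path(pop_seq, extra_center=None, extra_col=None):
        cs = [centers[p] for p in pop_seq]
        cols = anchors[:, [pop_col[p] for p in pop_seq]]
        if extra_center is not None:
            cs = cs + [extra_center]
            cols = np.column_stack([cols, extra_col])
        return np.asarray(cs), cols

    head_osteo, head_adipo = params.branch_osteo[0], params.branch_adipo[0]
    head_avg = 0.5 * (anchors[:, pop_col[head_osteo]] + anchors[:, pop_col[head_adipo]])
    head_center = 0.5 * (centers[head_osteo] + centers[head_adipo])
    paths = {
        "trunk": _path(list(params.trunk), head_center, head_avg),
        "osteo": _path(list(params.trunk) + list(params.branch_osteo)),
        "adipo": _path(list(params.trunk) + list(params.branch_adipo)),
    }

    log_mu = np.empty((n_genes, n_cells))
    for name, (cs, cols) in paths.items():
        cell_sel = np.where(branch == name)[0]
        if cell_sel.size == 0:
            continue
        t = np.clip(pseudotime[cell_sel], cs[0], cs[-1])
        right = np.clip(np.searchsorted(cs, t), 1, len(cs) - 1)
        left = right - 1
        w = (t - cs[left]) / (cs[right] - cs[left])
        log_mu[:, cell_sel] = cols[:, left] * (1.0 - w) + cols[:, right] * w

    s_cells = np.where(cycling & (phase == "S"))[0]
    g2m_cells = np.where(cycling & (phase == "G2M"))[0]
    log_mu[np.ix_(s_idx, s_cells)] += params.cycle_effect_delta
    log_mu[np.ix_(g2m_idx, g2m_cells)] += params.cycle_effect_delta

    # --- counts ---------------------------------------------------------
    rel = np.exp(log_mu)
    rel /= rel.sum(axis=0, keepdims=True)
    mu_lib, sigma_lib = params.libsize_lognormal_mu_sigma
    libsize = rng.lognormal(mean=mu_lib, sigma=sigma_lib, size=n_cells)
    mean_counts = rel * libsize[None, :]

    phi = params.nb_dispersion
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mean_counts * phi)
    else:
        lam = mean_counts
    counts = rng.poisson(lam).astype(np.int64)

    cell_ids = pd.Index([f"Cell{i + 1:05d}" for i in range(n_cells)])
    matrix = CountMatrix(sp.csr_matrix(counts), pd.Index(gene_ids), cell_ids)

    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "population": population,
            "pseudotime": pseudotime,
            "branch": branch,
            "cycling": cycling,
            "cycle_phase": phase,
            "libsize": libsize,
        }
    )
    genes = pd.DataFrame(
        {"gene_id": gene_ids, "program": program, "base_log_mean": base_log}
    )
    truth = SimTruth(cells=cells, genes=genes, expected_counts=mean_counts, params=params)
    return matrix, truth


def write_fixture(
    dataset: CountMatrix, truth: SimTruth, directory: str | os.PathLike
) -> dict[str, Path]:
    """Write a complete on-disk fixture: 10x trio, truth tables, gene-set files.

    Returns a name -> path map of everything written.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_10x_mtx(dataset, directory)
    paths = {
        "matrix": directory / "matrix.mtx",
        "features": directory / "features.tsv",
        "barcodes": directory / "barcodes.tsv",
        "cells_truth": directory / "cells_truth.tsv",
        "genes_truth": directory / "genes_truth.tsv",
        "s_genes": directory / "s_genes.txt",
        "g2m_genes": directory / "g2m_genes.txt",
    }
    truth.cells.to_csv(paths["cells_truth"], sep="\t", index=False)
    truth.genes.to_csv(paths["genes_truth"], sep="\t", index=False)
    paths["s_genes"].write_text("\n".join(truth.s_genes) + "\n")
    paths["g2m_genes"].write_text("\n".join(truth.g2m_genes) + "\n")
    return paths
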