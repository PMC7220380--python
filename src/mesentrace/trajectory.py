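"""Cluster-centroid MST trajectory, lineages, and arc-length pseudotime.

The lineage backbone is the minimum spanning tree over cluster centroids in
a reduced space (top PCs by default). Rooting the tree at a user-designated
progenitor cluster turns each root-to-leaf path into a lineage; nodes of
degree >= 3 along those paths are branch points. Each cell is orthogonally
projected onto the nearest segment of its lineage's piecewise-linear
centroid path and its pseudotime is the arc length from the root start to
the projection. In the bone-marrow mesenchymal setting this produces the
expected Y: early progenitors at the origin, osteocytes and adipocytes at
the two divergent ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cluster import ClusterAssignment

__all__ = ["LineageTree", "PseudotimeAssignment", "build_mst", "extract_lineages", "assign_pseudotime"]


@dataclass
class LineageTree:
    """Cluster-level spanning tree, optionally rooted with extracted lineages."""

    centroids: dict  # cluster id -> coordinate vector
    edges: list  # (u, v, length) with u < v
    root: int | None = None
    lineages: dict = field(default_factory=dict)  # lineage id -> ordered cluster path
    branch_points: list = field(default_factory=list)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.centroids)
        for u, v, w in self.edges:
            g.add_edge(u, v, length=w)
        return g

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))


@dataclass
class PseudotimeAssignment:
    """Per-cell pseudotime, branch id, and projection segment.

    Columns of ``table``: cell_id, cluster, pseudotime, branch, segment
    (the '(u,v)' cluster pair the cell projects onto).
    """

    table: pd.DataFrame


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def cluster_centroids(coords: np.ndarray, clusters: ClusterAssignment) -> dict:
    """Mean coordinate of each cluster in the reduced space."""
    coords = np.asarray(coords, dtype=float)
    labels = clusters.labels.to_numpy()
    return {int(c): coords[labels == c].mean(axis=0) for c in np.unique(labels)}


def build_mst(coords: np.ndarray, clusters: ClusterAssignment) -> LineageTree:
    """Minimum spanning tree over cluster centroids (Euclidean lengths).

    Kruskal with deterministic tie-breaking: edges sorted by
    (length, smaller id, larger id).
    """
    cents = cluster_centroids(coords, clusters)
    ids = sorted(cents)
    if len(ids) < 2:
        raise ValueError("trajectory needs at least 2 clusters")
    candidates = []
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            d = float(np.linalg.norm(cents[u] - cents[v]))
            candidates.append((d, u, v))
    candidates.sort()
    uf = _UnionFind(ids)
    edges = []
    for d, u, v in candidates:
        if uf.union(u, v):
            edges.append((u, v, d))
        if len(edges) == len(ids) - 1:
            break
    return LineageTree(centroids=cents, edges=edges)


def extract_lineages(tree: LineageTree, root_cluster: int) -> LineageTree:
    """Root the tree: one lineage per root-to-leaf path, branch points flagged.

    Lineages are named after their terminal cluster (``to_<leaf>``). A
    single-edge tree rooted at one end yields one lineage.
    """
    g = tree.graph()
    if root_cluster not in g:
        raise ValueError(f"root cluster {root_cluster} is not a node of the tree")
    leaves = sorted(n for n in g.nodes if g.degree(n) == 1 and n != root_cluster)
    if not leaves:  # degenerate: root is the only node or the sole leaf
        leaves = [n for n in g.nodes if n != root_cluster]
    lineages = {}
    for leaf in leaves:
        path = nx.shortest_path(g, root_cluster, leaf)
        lineages[f"to_{leaf}"] = path
    on_paths = set().union(*lineages.values()) if lineages else set()
    branch_points = sorted(n for n in on_paths if g.degree(n) >= 3)
    return LineageTree(
        centroids=tree.centroids,
        edges=tree.edges,
        root=root_cluster,
        lineages=lineages,
        branch_points=branch_points,
    )


def _project_to_segment(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(distance, t) of the clamped orthogonal projection of p onto segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return float(np.linalg.norm(p - proj)), t


def assign_pseudotime(
    coords: np.ndarray, clusters: ClusterAssignment, tree: LineageTree
) -> PseudotimeAssignment:
    """Arc-length pseudotime along the rooted piecewise-linear centroid paths.

    Each cell is projected onto the nearest segment among the lineage paths
    its cluster belongs to; pseudotime is the arc length from the root
    start to the projection point. Cells in clusters shared by every
    lineage (before the first branch point) get branch id 'trunk'; cells
    past it get their lineage id.
    """
    if tree.root is None or not tree.lineages:
        raise ValueError("tree must be rooted (call extract_lineages first)")
    coords = np.asarray(coords, dtype=float)
    labels = clusters.labels

    # segment tables per lineage: (a, b, cum_start, length, (u, v))
    seg_tables: dict[str, list] = {}
    for lid, path in tree.lineages.items():
        segs, cum = [], 0.0
        for u, v in zip(path[:-1], path[1:]):
            a, b = tree.centroids[u], tree.centroids[v]
            length = float(np.linalg.norm(b - a))
            segs.append((a, b, cum, length, (u, v)))
            cum += length
        seg_tables[lid] = segs

    # which lineages contain each cluster; trunk = clusters on all lineages
    lineage_of_cluster: dict[int, list[str]] = {}
    for lid, path in tree.lineages.items():
        for c in path:
            lineage_of_cluster.setdefault(c, []).append(lid)
    n_lineages = len(tree.lineages)

    records = []
    for cell_id, cl in labels.items():
        cl = int(cl)
        lids = lineage_of_cluster.get(cl)
        if lids is None:
            raise ValueError(f"cluster {cl} lies on no lineage; tree does not span it")
        p = coords[labels.index.get_loc(cell_id)]
        best = None
        for lid in lids:
            for a, b, cum, length, seg in seg_tables[lid]:
                d, t = _project_to_segment(p, a, b)
                pt = cum + t * length
                key = (d, pt)
                if best is None or key < best[0]:
                    best = (key, pt, seg)
        _, pt, seg = best
        branch = "trunk" if len(lids) == n_lineages else lids[0]
        records.append((cell_id, cl, pt, branch, f"({seg[0]},{seg[1]})"))
    table = pd.DataFrame(
        records, columns=["cell_id", "cluster", "pseudotime", "branch", "segment"]
    )
    return PseudotimeAssignment(table)
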