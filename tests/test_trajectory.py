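import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mesentrace.cluster import ClusterAssignment
from mesentrace.trajectory import (
    LineageTree,
    assign_pseudotime,
    build_mst,
    extract_lineages,
)


def _assignment(labels):
    return ClusterAssignment(pd.Series(labels, index=[f"c{i}" for i in range(len(labels))]))


def _tree_from_centroids(centroids, edges, root=None, lineages=None, branch_points=None):
    return LineageTree(
        centroids={k: np.asarray(v, dtype=float) for k, v in centroids.items()},
        edges=edges,
        root=root,
        lineages=lineages or {},
        branch_points=branch_points or [],
    )


def brute_force_mst_weight(centroids):
    """Minimum spanning-tree weight by enumerating all Prüfer sequences."""
    ids = sorted(centroids)
    n = len(ids)
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = {i: 1 for i in range(n)}
        for s in seq:
            degree[s] += 1
        seq_list = list(seq)
        edges = []
        avail = sorted(i for i in range(n) if degree[i] == 1)
        deg = dict(degree)
        for s in seq_list:
            leaf = min(i for i in range(n) if deg[i] == 1)
            edges.append((leaf, s))
            deg[leaf] -= 1
            deg[s] -= 1
        last = [i for i in range(n) if deg[i] == 1]
        edges.append((last[0], last[1]))
        w = sum(np.linalg.norm(centroids[ids[a]] - centroids[ids[b]]) for a, b in edges)
        best = min(best, w)
    return best


class TestBuildMST:
    def test_collinear_centroids_form_a_path(self):
        coords = np.array([[0.0, 0], [0, 0], [5, 0], [5, 0], [9, 0], [9, 0]])
        tree = build_mst(coords, _assignment([0, 0, 1, 1, 2, 2]))
        assert sorted((u, v) for u, v, _ in tree.edges) == [(0, 1), (1, 2)]

    def test_two_clusters_single_edge(self):
        coords = np.array([[0.0, 0], [1, 1]])
        tree = build_mst(coords, _assignment([0, 1]))
        assert len(tree.edges) == 1

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_mst(np.zeros((3, 2)), _assignment([0, 0, 0]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weight_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(5, 3))
        tree = build_mst(coords, _assignment(list(range(5))))
        cents = {i: coords[i] for i in range(5)}
        assert tree.total_weight == pytest.approx(brute_force_mst_weight(cents))

    def test_deterministic_tie_break(self):
        # unit square: four edges of length 1; Kruskal keeps (0,1),(0,2),(1,3)
        coords = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1]])
        tree = build_mst(coords, _assignment([0, 1, 2, 3]))
        assert sorted((u, v) for u, v, _ in tree.edges) == [(0, 1), (0, 2), (1, 3)]


class TestExtractLineages:
    def _y_tree(self):
        cents = {0: [0.0, 0], 1: [1.0, 0], 2: [2.0, 1], 3: [2.0, -1]}
        edges = [(0, 1, 1.0), (1, 2, np.sqrt(2)), (1, 3, np.sqrt(2))]
        return _tree_from_centroids(cents, edges)

    def test_y_tree_rooted_at_stem_gives_two_lineages(self):
        rooted = extract_lineages(self._y_tree(), 0)
        assert set(rooted.lineages) == {"to_2", "to_3"}
        assert rooted.lineages["to_2"] == [0, 1, 2]
        assert rooted.branch_points == [1]

    def test_path_graph_has_one_lineage(self):
        cents = {0: [0.0], 1: [1.0], 2: [2.0]}
        tree = _tree_from_centroids(cents, [(0, 1, 1.0), (1, 2, 1.0)])
        rooted = extract_lineages(tree, 0)
        assert rooted.lineages == {"to_2": [0, 1, 2]}
        assert rooted.branch_points == []

    def test_star_rooted_at_center_has_three_lineages(self):
        cents = {0: [0.0, 0], 1: [1.0, 0], 2: [0.0, 1], 3: [-1.0, 0]}
        tree = _tree_from_centroids(cents, [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])
        rooted = extract_lineages(tree, 0)
        assert len(rooted.lineages) == 3
        assert rooted.branch_points == [0]

    def test_missing_root_rejected(self):
        with pytest.raises(ValueError, match="root"):
            extract_lineages(self._y_tree(), 9)


class TestAssignPseudotime:
    def _rooted_path(self):
        # segments of length 2 then 4 along the x axis
        cents = {0: [0.0, 0], 1: [2.0, 0], 2: [6.0, 0]}
        tree = _tree_from_centroids(
            cents,
            [(0, 1, 2.0), (1, 2, 4.0)],
            root=0,
            lineages={"to_2": [0, 1, 2]},
        )
        return tree

    def test_cell_at_root_centroid_gets_zero(self):
        tree = self._rooted_path()
        coords = np.array([[0.0, 0], [2.0, 0], [6.0, 0]])
        pt = assign_pseudotime(coords, _assignment([0, 1, 2]), tree)
        assert pt.table["pseudotime"].iloc[0] == 0.0

    def test_terminal_centroid_gets_total_arc_length(self):
        tree = self._rooted_path()
        coords = np.array([[0.0, 0], [2.0, 0], [6.0, 0]])
        pt = assign_pseudotime(coords, _assignment([0, 1, 2]), tree)
        assert pt.table["pseudotime"].iloc[2] == pytest.approx(6.0)

    def test_midpoint_of_second_segment_hand_value(self):
        """A cell halfway along a length-4 segment that follows a length-2
        segment sits at arc length 2 + 2 = 4."""
        tree = self._rooted_path()
        coords = np.array([[0.0, 0], [4.0, 0.5], [6.0, 0]])
        pt = assign_pseudotime(coords, _assignment([0, 1, 2]), tree)
        assert pt.table["pseudotime"].iloc[1] == pytest.approx(4.0)

    def test_unrooted_tree_rejected(self):
        cents = {0: [0.0], 1: [1.0]}
        tree = _tree_from_centroids(cents, [(0, 1, 1.0)])
        with pytest.raises(ValueError, match="rooted"):
            assign_pseudotime(np.zeros((2, 1)), _assignment([0, 1]), tree)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(60, 2))
        labels = rng.integers(0, 3, 60)
        labels[:3] = [0, 1, 2]
        ca = _assignment(labels)
        tree = extract_lineages(build_mst(coords, ca), 0)
        pt1 = assign_pseudotime(coords, ca, tree)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = coords @ R.T + np.array([5.0, -3.0])
        tree2 = extract_lineages(build_mst(moved, ca), 0)
        pt2 = assign_pseudotime(moved, ca, tree2)
        np.testing.assert_allclose(
            pt1.table["pseudotime"], pt2.table["pseudotime"], atol=1e-8
        )


class TestDefaultFixtureRecovery:
    def test_two_lineages_end_at_planted_termini_with_correlated_pseudotime(
        self, default_processed, population_clusters
    ):
        ca, code = population_clusters
        pcs = default_processed["pcs"]
        tc = default_processed["truth_cells"]
        tree = extract_lineages(build_mst(pcs, ca), code["EMP"])
        assert len(tree.lineages) == 2
        leaves = {path[-1] for path in tree.lineages.values()}
        assert leaves == {code["Ocy"], code["AD"]}
        pt = assign_pseudotime(pcs, ca, tree).table.set_index("cell_id")
        for path in tree.lineages.values():
            mask = pt["cluster"].isin(path)
            rho = spearmanr(
                pt.loc[mask, "pseudotime"], tc.loc[mask[mask].index, "pseudotime"]
            )[0]
            assert abs(rho) >= 0.8
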