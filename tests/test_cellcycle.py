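import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mesentrace as mt
from mesentrace.cellcycle import (
    classify_proliferative,
    filter_cycle_genes,
    permutation_pvalue,
    proliferative_fraction,
    score_cells,
)
from mesentrace.cluster import ClusterAssignment
from mesentrace.io import GeneSetPair
from mesentrace.qc import NormalizedMatrix


def exhaustive_oracle(values, n_s):
    """Independent enumeration of all label splits (mean difference, |.| counting)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    obs = values[:n_s].mean() - values[n_s:].mean()
    count = total = 0
    for comb in combinations(range(n), n_s):
        in_s = np.zeros(n, dtype=bool)
        in_s[list(comb)] = True
        d = values[in_s].mean() - values[~in_s].mean()
        total += 1
        if abs(d) >= abs(obs) - 1e-12:
            count += 1
    return obs, count / total


def _clusters(labels):
    return ClusterAssignment(pd.Series(labels, index=[f"c{i}" for i in range(len(labels))]))


class TestFilterCycleGenes:
    def _norm(self, prevalences, n_cells=100):
        X = np.zeros((len(prevalences), n_cells))
        for i, pr in enumerate(prevalences):
            X[i, : int(round(pr * n_cells))] = 1.0
        return NormalizedMatrix(X, [f"g{i}" for i in range(len(prevalences))],
                                [f"c{j}" for j in range(n_cells)])

    def test_low_prevalence_gene_dropped(self):
        norm = self._norm([0.04, 0.5, 0.6, 0.7])
        sets = GeneSetPair(["g0", "g1"], ["g2", "g3"])
        used = filter_cycle_genes(norm, sets)
        assert used.s_used == ["g1"]
        assert "g0" in used.dropped

    def test_ubiquitous_sets_keep_full_sizes(self):
        """43 + 54 ubiquitously expressed genes all survive the 5% filter."""
        norm = self._norm([1.0] * 97)
        sets = GeneSetPair([f"g{i}" for i in range(43)], [f"g{i}" for i in range(43, 97)])
        used = filter_cycle_genes(norm, sets)
        assert (used.n_s, used.n_g2m) == (43, 54)

    def test_zero_min_prevalence_is_identity(self):
        norm = self._norm([0.01, 0.02, 0.03, 0.04])
        sets = GeneSetPair(["g0", "g1"], ["g2", "g3"])
        used = filter_cycle_genes(norm, sets, min_prevalence=0.0)
        assert used.n_total == 4

    def test_empty_filtered_set_rejected(self):
        norm = self._norm([0.01, 0.5])
        sets = GeneSetPair(["g0"], ["g1"])
        with pytest.raises(ValueError, match="empty"):
            filter_cycle_genes(norm, sets)


class TestPermutationPvalue:
    def test_hand_toy_matches_enumeration_oracle(self):
        values = [10.0, 10.0, 0.0, 0.0, 0.0]
        obs_oracle, p_oracle = exhaustive_oracle(values, 2)
        obs, p = permutation_pvalue(values, 2, exhaustive="on")
        assert obs == pytest.approx(obs_oracle) == 10.0
        assert p == pytest.approx(p_oracle) == 0.1

    def test_equal_values_give_p_one(self):
        obs, p = permutation_pvalue(np.ones(79), 34, B=2000, seed=0, exhaustive="auto")
        assert obs == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_exhaustive_mode_guards_against_huge_enumerations(self):
        with pytest.raises(ValueError, match="exceeds"):
            permutation_pvalue(np.ones(79), 34, exhaustive="on")

    def test_monte_carlo_floor_is_add_one(self):
        x = np.concatenate([np.full(34, 100.0), np.zeros(45)])
        _, p = permutation_pvalue(x, 34, B=5000, seed=0, exhaustive="off")
        assert p == pytest.approx(1 / 5001)

    def test_monte_carlo_close_to_exhaustive(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n_tot = int(rng.integers(5, 13))
            n_s = int(rng.integers(1, n_tot))
            x = rng.gamma(2.0, 1.0, n_tot)
            _, pe = permutation_pvalue(x, n_s, exhaustive="on")
            _, pm = permutation_pvalue(x, n_s, B=5000, seed=int(rng.integers(2**31)), exhaustive="off")
            bound = 3 * math.sqrt(max(pe * (1 - pe), 0.0) / 5000) + 2 / 5001
            assert abs(pm - pe) <= bound

    def test_degenerate_set_sizes_rejected(self):
        with pytest.raises(ValueError, match="n_s"):
            permutation_pvalue(np.ones(5), 0)
        with pytest.raises(ValueError, match="n_s"):
            permutation_pvalue(np.ones(5), 5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=6, max_size=10),
           st.integers(2, 4))
    def test_label_exchange_flips_sign_keeps_p(self, values, n_s):
        """Swapping the S/G2M roles negates the observed diff, preserves p."""
        x = np.asarray(values)
        n_g = len(x) - n_s
        obs1, p1 = permutation_pvalue(x, n_s, exhaustive="on")
        swapped = np.concatenate([x[n_s:], x[:n_s]])
        obs2, p2 = permutation_pvalue(swapped, n_g, exhaustive="on")
        assert obs2 == pytest.approx(-obs1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_shared_resamples_are_deterministic(self):
        rng = np.random.default_rng(13)
        X = rng.gamma(2, 1, size=(8, 20))
        a = score_cells(X, 7, B=500, seed=9, exhaustive="off")
        b = score_cells(X, 7, B=500, seed=9, exhaustive="off")
        np.testing.assert_array_equal(a[1], b[1])


class TestClassifyProliferative:
    def test_all_null_cluster_has_no_calls(self):
        calls = classify_proliferative(np.zeros(100), np.ones(100), _clusters([0] * 100))
        assert calls.table["proliferative"].sum() == 0
        assert (calls.table["dominant_set"] == "none").all()

    def test_hand_bh_computation(self):
        """10 cells at p=0.001 among 90 at p=1: BH-adjusted 0.001*100/10 = 0.01."""
        pvals = np.array([0.001] * 10 + [1.0] * 90)
        obs = np.array([1.0] * 10 + [0.0] * 90)
        calls = classify_proliferative(obs, pvals, _clusters([0] * 100), alpha=0.05)
        t = calls.table
        assert t["fdr"][:10].to_numpy() == pytest.approx(0.01)
        assert t["proliferative"].sum() == 10
        assert (t["dominant_set"][:10] == "S").all()

    def test_bh_applied_per_cluster_not_globally(self):
        # same p in a small vs large cluster: small cluster has fewer tests
        pvals = np.array([0.01] + [1.0] * 9 + [0.01] + [1.0] * 89)
        obs = np.ones(100)
        labels = [0] * 10 + [1] * 90
        calls = classify_proliferative(obs, pvals, _clusters(labels), alpha=0.05)
        t = calls.table
        assert t["fdr"].iloc[0] == pytest.approx(0.1)  # 0.01 * 10 / 1
        assert t["fdr"].iloc[10] == pytest.approx(0.9)  # 0.01 * 90 / 1

    def test_alpha_zero_flags_nothing(self):
        pvals = np.full(20, 1e-6)
        calls = classify_proliferative(np.ones(20), pvals, _clusters([0] * 20), alpha=0.0)
        assert calls.table["proliferative"].sum() == 0


class TestProliferativeFraction:
    def test_hand_counted_fractions(self):
        labels = [0] * 10 + [1] * 10
        pvals = np.array([1e-6] * 4 + [1.0] * 6 + [1e-6] * 10)
        obs = np.ones(20)
        calls = classify_proliferative(obs, pvals, _clusters(labels), alpha=0.05)
        frac = proliferative_fraction(calls).set_index("cluster")
        assert frac.loc[0, "fraction"] == pytest.approx(0.4)
        assert frac.loc[1, "fraction"] == pytest.approx(1.0)
        assert frac["fraction"].between(0, 1).all()


def test_planted_cycling_cells_detected_and_termini_quiet(default_processed):
    """Sensitivity >= 0.9 for planted cyclers; Ocy/AD-like fractions ~ 0."""
    norm = default_processed["norm"]
    tc = default_processed["truth_cells"]
    truth = default_processed["truth"]
    used = filter_cycle_genes(norm, GeneSetPair(truth.s_genes, truth.g2m_genes))
    idx = norm.gene_ids.get_indexer(used.s_used + used.g2m_used)
    obs, pvals = score_cells(norm.values[idx].T, used.n_s, B=5000, seed=2)
    labels = pd.Series(pd.factorize(tc["population"])[0], index=tc.index)
    calls = classify_proliferative(obs, pvals, ClusterAssignment(labels))
    flagged = calls.table.set_index("cell_id")["proliferative"]
    cycling = tc["cycling"]
    assert flagged[cycling].mean() >= 0.9
    for pop in ("Ocy", "AD"):
        assert flagged[tc["population"] == pop].mean() <= 0.01
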