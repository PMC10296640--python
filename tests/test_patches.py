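"""Cluster splitting, patch extraction, Mann-Whitney scoring, iteration."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from casurf.errors import DegenerateSplitError, ScoringError
from casurf.patches import (extract_patch, iterate_patches,
                            mann_whitney_greater, score_patch, split_clusters)
from casurf.tac import build_tac_graph, eigenvector_centrality


def oracle_split(scores):
    """Exhaustive threshold-split oracle: minimum total within-cluster SS."""
    nodes = sorted(scores, key=lambda n: (scores[n], n))
    values = [scores[n] for n in nodes]
    best = None
    for k in range(1, len(values)):
        ss = (np.var(values[:k]) * k) + (np.var(values[k:]) * (len(values) - k))
        if best is None or ss < best[0] - 1e-12:
            best = (ss, k)
    k = best[1]
    return set(nodes[k:]), set(nodes[:k])


class TestSplitClusters:
    def test_perfectly_separated(self):
        scores = {1: 0.0, 2: 0.0, 3: 1.0, 4: 1.0}
        high, low = split_clusters(scores)
        assert high == {3, 4} and low == {1, 2}

    def test_known_hand_case(self):
        scores = dict(enumerate([0.1, 0.15, 0.2, 0.8, 0.9]))
        high, low = split_clusters(scores)
        assert high == {3, 4}

    def test_degenerate_identical_scores(self):
        with pytest.raises(DegenerateSplitError):
            split_clusters({i: 0.5 for i in range(5)})

    @pytest.mark.parametrize("n", [5, 20, 87, 200])
    def test_matches_exhaustive_threshold_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            scores = {i: float(v) for i, v in
                      enumerate(rng.uniform(0, 1, size=n))}
            high, low = split_clusters(scores)
            o_high, o_low = oracle_split(scores)
            assert high == o_high and low == o_low

    def test_optimal_split_is_contiguous(self):
        rng = np.random.default_rng(17)
        scores = {i: float(v) for i, v in enumerate(rng.normal(size=50))}
        high, low = split_clusters(scores)
        assert min(scores[n] for n in high) >= max(scores[n] for n in low)


class TestExtractPatch:
    def _path_graph(self, conservation):
        n = len(conservation)
        adjacency = frozenset(frozenset((i, i + 1)) for i in range(n - 1))
        return build_tac_graph(frozenset(range(n)), adjacency, conservation)

    def test_connected_high_set_returned_whole(self):
        graph = self._path_graph({i: 0.5 for i in range(6)})
        centrality = {0: 0.1, 1: 0.2, 2: 0.8, 3: 0.9, 4: 0.85, 5: 0.1}
        patch = extract_patch(graph, centrality, {2, 3, 4})
        assert patch == frozenset({2, 3, 4})

    def test_disconnected_high_set_keeps_top_component(self):
        graph = self._path_graph({i: 0.5 for i in range(7)})
        centrality = {0: 0.9, 1: 0.8, 2: 0.1, 3: 0.1, 4: 0.7, 5: 0.75, 6: 0.95}
        # high set splits into {0,1} and {4,5,6}; the top node 6 wins
        patch = extract_patch(graph, centrality, {0, 1, 4, 5, 6})
        assert patch == frozenset({4, 5, 6})

    def test_top_node_in_smaller_component(self):
        graph = self._path_graph({i: 0.5 for i in range(7)})
        centrality = {0: 0.99, 1: 0.1, 2: 0.6, 3: 0.1, 4: 0.7, 5: 0.72, 6: 0.71}
        patch = extract_patch(graph, centrality, {0, 4, 5, 6})
        assert patch == frozenset({0})

    def test_singleton_high_set(self):
        graph = self._path_graph({i: 0.5 for i in range(3)})
        patch = extract_patch(graph, {0: 0.1, 1: 0.9, 2: 0.1}, {1})
        assert patch == frozenset({1})

    def test_patch_matches_bfs_oracle(self):
        rng = np.random.default_rng(23)
        g = nx.random_geometric_graph(40, 0.3, seed=5)
        adjacency = frozenset(frozenset(e) for e in g.edges)
        conservation = {n: 0.5 for n in g.nodes}
        graph = build_tac_graph(frozenset(g.nodes), adjacency, conservation)
        centrality = {n: float(rng.uniform()) for n in g.nodes}
        high = {n for n in g.nodes if centrality[n] > 0.6}
        if not high:
            pytest.skip("empty high set for this draw")
        patch = extract_patch(graph, centrality, high)
        seed = max(high, key=centrality.get)
        component = nx.node_connected_component(g.subgraph(high), seed)
        assert patch == frozenset(component)


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        p = mann_whitney_greater(np.array([0.9, 0.8, 0.85]),
                                 np.array([0.1, 0.2, 0.15]))
        assert p == pytest.approx(1 / 20)

    def test_all_tied_carries_no_evidence(self):
        p = mann_whitney_greater(np.full(4, 0.5), np.full(6, 0.5))
        assert p == 1.0

    def test_exact_equals_enumeration_with_ties(self):
        patch = np.array([0.5, 0.7, 0.7])
        rest = np.array([0.5, 0.3, 0.7, 0.2])
        pooled = np.concatenate([patch, rest])
        ranks = rankdata(pooled)
        n = len(patch)
        u_obs = ranks[:n].sum() - n * (n + 1) / 2
        count = total = 0
        for idx in combinations(range(len(pooled)), n):
            u = ranks[list(idx)].sum() - n * (n + 1) / 2
            total += 1
            count += u >= u_obs - 1e-9
        assert mann_whitney_greater(patch, rest) == pytest.approx(count / total)

    @pytest.mark.parametrize("sizes", [(8, 10), (10, 12), (15, 9)])
    def test_normal_approximation_close_to_exact(self, sizes):
        n, m = sizes
        rng = np.random.default_rng(n * m)
        for _ in range(5):
            a = rng.normal(0.6, 0.2, n)
            b = rng.normal(0.4, 0.2, m)
            exact = mannwhitneyu(a, b, alternative="greater",
                                 method="exact").pvalue
            approx = mann_whitney_greater(a, b) if min(n, m) > 8 else \
                mannwhitneyu(a, b, alternative="greater",
                             method="asymptotic").pvalue
            assert abs(approx - exact) < 0.01


class TestScorePatch:
    def test_absolute_and_relative_means(self):
        cons = {1: 0.8, 2: 0.8, 3: 0.8, 4: 0.3, 5: 0.3, 6: 0.3}
        absolute, relative, _p = score_patch(frozenset({1, 2, 3}), cons)
        assert absolute == pytest.approx(0.8)
        assert relative == pytest.approx(0.5)

    def test_hand_case_with_exact_p(self):
        cons = {1: 0.9, 2: 0.8, 3: 0.85, 4: 0.1, 5: 0.2, 6: 0.15}
        absolute, relative, p = score_patch(frozenset({1, 2, 3}), cons)
        assert relative == pytest.approx(0.7)
        assert p == pytest.approx(0.05)

    def test_empty_rest_is_error(self):
        with pytest.raises(ScoringError):
            score_patch(frozenset({1, 2}), {1: 0.5, 2: 0.6})


class TestIteratePatches:
    def _two_island_inputs(self):
        """6x4 grid surface with two separated conserved islands."""
        g = nx.grid_2d_graph(6, 4)
        relabel = {node: i for i, node in enumerate(sorted(g.nodes))}
        g = nx.relabel_nodes(g, relabel)
        adjacency = frozenset(frozenset(e) for e in g.edges)
        conservation = {n: 0.3 for n in g.nodes}
        island_a = {0, 1, 4, 5}        # rows 0-1, cols 0-1
        island_b = {18, 19, 22, 23}    # rows 4-5, cols 2-3
        for n in island_a:
            conservation[n] = 0.95
        for n in island_b:
            conservation[n] = 0.75
        return frozenset(g.nodes), adjacency, conservation, island_a, island_b

    def test_two_islands_recovered_in_strength_order(self):
        nodes, adjacency, conservation, a, b = self._two_island_inputs()
        patches = iterate_patches(nodes, adjacency, conservation,
                                  max_patches=2, p_cutoff=1.0)
        assert len(patches) == 2
        assert a <= set(patches[0].residues)
        assert b <= set(patches[1].residues)
        assert patches[0].absolute_conservation > patches[1].absolute_conservation

    def test_successive_patches_disjoint(self):
        nodes, adjacency, conservation, *_ = self._two_island_inputs()
        patches = iterate_patches(nodes, adjacency, conservation,
                                  max_patches=4, p_cutoff=1.0)
        seen = set()
        for patch in patches:
            assert not (seen & patch.residues)
            seen |= patch.residues
        assert seen <= nodes

    def test_max_patches_bounds_iterations(self):
        nodes, adjacency, conservation, *_ = self._two_island_inputs()
        patches = iterate_patches(nodes, adjacency, conservation,
                                  max_patches=1, p_cutoff=1.0)
        assert len(patches) == 1

    def test_nonsignificant_patch_reported_and_halts(self):
        nodes, adjacency, conservation, *_ = self._two_island_inputs()
        patches = iterate_patches(nodes, adjacency, conservation,
                                  max_patches=5, p_cutoff=1e-30)
        assert len(patches) == 1
        assert not patches[0].significant

    def test_patch_connected_in_graph(self):
        nodes, adjacency, conservation, *_ = self._two_island_inputs()
        patches = iterate_patches(nodes, adjacency, conservation,
                                  max_patches=2, p_cutoff=1.0)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(tuple(p) for p in adjacency)
        for patch in patches:
            assert nx.is_connected(g.subgraph(patch.residues))
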