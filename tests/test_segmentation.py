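"""Module segmentation: PAE graph construction and community detection."""

import networkx as nx
import numpy as np
import pytest

from casurf.segmentation import (build_pae_graph, detect_communities,
                                 filter_modules, optimize_resolution)
from casurf.structure_io import PAEMatrix
from casurf.synthetic import FixtureSpec, make_structure


def all_partitions(items):
    """Every set partition of ``items`` (independent brute-force oracle)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in all_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] | {first}] + partition[i + 1:]
        yield partition + [{first}]


def best_modularity(graph, resolution=1.0):
    return max(nx.community.modularity(graph, p, weight="weight",
                                       resolution=resolution)
               for p in all_partitions(graph.nodes))


def two_cliques_graph(k=5):
    g = nx.Graph()
    for base in (0, k):
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(base + i, base + j, weight=1.0)
    g.add_edge(0, k, weight=0.1)  # weak bridge
    return g


class TestBuildPaeGraph:
    def _protein(self, plddt_values):
        spec = FixtureSpec(seed=2, residues_per_module=len(plddt_values))
        protein = make_structure(spec)
        for i, v in enumerate(plddt_values, 1):
            protein.structure.plddt[("A", i)] = v
        return protein

    def test_plddt_filter_is_strict(self):
        protein = self._protein([80.0, 60.0, 90.0] + [85.0] * 57)
        graph = build_pae_graph(protein.structure, protein.pae)
        assert 2 not in graph.nodes
        assert {1, 3} <= set(graph.nodes)

    def test_plddt_exactly_at_threshold_excluded(self):
        protein = self._protein([70.0] + [85.0] * 59)
        graph = build_pae_graph(protein.structure, protein.pae)
        assert 1 not in graph.nodes

    def test_all_pae_above_threshold_gives_edgeless_graph(self):
        protein = self._protein([85.0] * 60)
        pae = PAEMatrix(np.full((60, 60), 10.0))
        graph = build_pae_graph(protein.structure, pae)
        assert graph.number_of_nodes() == 60
        assert graph.number_of_edges() == 0

    def test_pae_exactly_at_threshold_excluded(self):
        protein = self._protein([85.0] * 60)
        pae = PAEMatrix(np.full((60, 60), 5.0))
        graph = build_pae_graph(protein.structure, pae)
        assert graph.number_of_edges() == 0

    def test_asymmetric_pae_symmetrised_by_mean(self):
        protein = self._protein([85.0] * 60)
        values = np.full((60, 60), 10.0)
        values[0, 1], values[1, 0] = 2.0, 4.0
        graph = build_pae_graph(protein.structure, PAEMatrix(values))
        assert graph[1][2]["weight"] == pytest.approx(1.0 / 3.0)

    def test_near_zero_pae_is_floored_before_inversion(self):
        protein = self._protein([85.0] * 60)
        values = np.full((60, 60), 10.0)
        values[0, 1] = values[1, 0] = 0.01
        graph = build_pae_graph(protein.structure, PAEMatrix(values))
        assert graph[1][2]["weight"] == pytest.approx(1.0 / 0.2)

    def test_dimension_mismatch_is_error(self):
        protein = self._protein([85.0] * 60)
        with pytest.raises(Exception):
            build_pae_graph(protein.structure, PAEMatrix(np.zeros((5, 5))))


class TestDetectCommunities:
    def test_two_cliques_split_into_cliques(self):
        graph = two_cliques_graph(5)
        partition = detect_communities(graph, resolution=1.0)
        assert sorted(map(sorted, partition)) == [[0, 1, 2, 3, 4],
                                                  [5, 6, 7, 8, 9]]

    def test_greedy_close_to_exhaustive_optimum(self):
        # brute force over all set partitions is feasible on small graphs
        rng = np.random.default_rng(0)
        suite = [two_cliques_graph(4)]
        for trial in range(3):
            g = nx.gnp_random_graph(8, 0.45, seed=int(rng.integers(1e6)))
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.5, 2.0))
            if g.number_of_edges():
                suite.append(g)
        for graph in suite:
            partition = detect_communities(graph, resolution=1.0)
            got = nx.community.modularity(graph, partition, weight="weight")
            best = best_modularity(graph)
            assert got >= 0.95 * best

    def test_resolution_zero_gives_one_community(self):
        graph = nx.complete_graph(8)
        for u, v in graph.edges:
            graph[u][v]["weight"] = 1.0
        partition = detect_communities(graph, resolution=0.0)
        assert len(partition) == 1

    def test_edgeless_graph_gives_singletons(self):
        graph = nx.empty_graph(5)
        partition = detect_communities(graph, resolution=1.0)
        assert all(len(c) == 1 for c in partition)
        assert len(partition) == 5

    def test_partition_exhaustive_and_disjoint(self):
        graph = two_cliques_graph(5)
        partition = detect_communities(graph, resolution=1.0)
        union = set().union(*partition)
        assert union == set(graph.nodes)
        assert sum(map(len, partition)) == len(union)

    def test_modularity_beats_trivial_partitions(self):
        graph = two_cliques_graph(5)
        partition = detect_communities(graph, resolution=1.0)
        got = nx.community.modularity(graph, partition, weight="weight")
        one = nx.community.modularity(graph, [set(graph.nodes)], weight="weight")
        singles = nx.community.modularity(
            graph, [{n} for n in graph.nodes], weight="weight")
        assert got >= one and got >= singles

    def test_decreasing_resolution_never_adds_communities(self, default_protein):
        graph = build_pae_graph(default_protein.structure, default_protein.pae)
        counts = [len(detect_communities(graph, resolution=r))
                  for r in np.arange(1.0, -0.01, -0.1)]
        assert counts == sorted(counts, reverse=True)


class TestFilterModules:
    def _protein(self, n):
        return make_structure(FixtureSpec(seed=4, residues_per_module=n))

    def test_small_communities_dropped(self):
        protein = self._protein(74)
        partition = [frozenset(range(1, 46)), frozenset(range(46, 75))]
        modules = filter_modules(partition, protein.structure, protein.pae)
        assert len(modules) == 1 and modules[0].size == 45

    def test_boundary_thirty_retained(self):
        protein = self._protein(60)
        partition = [frozenset(range(1, 31)), frozenset(range(31, 61))]
        modules = filter_modules(partition, protein.structure, protein.pae,
                                 min_size=30)
        assert [m.size for m in modules] == [30, 30]

    def test_twenty_nine_dropped(self):
        protein = self._protein(60)
        partition = [frozenset(range(1, 30)), frozenset(range(30, 61))]
        modules = filter_modules(partition, protein.structure, protein.pae,
                                 min_size=30)
        assert [m.size for m in modules] == [31]

    def test_empty_partition_gives_empty_list(self):
        protein = self._protein(60)
        assert filter_modules([], protein.structure, protein.pae) == []

    def test_modules_annotated_and_ranked(self):
        protein = make_structure(FixtureSpec(seed=7, n_modules=2))
        partition = list(protein.module_residues)
        modules = filter_modules(partition, protein.structure, protein.pae)
        assert [m.rank for m in modules] == [1, 2]
        for m in modules:
            assert m.mean_pae < 5.0
            assert 70 < m.mean_plddt <= 100


class TestOptimizeResolution:
    def test_clique_domain_never_splits(self):
        protein = make_structure(FixtureSpec(seed=9, residues_per_module=30))
        pae = PAEMatrix(np.full((30, 30), 1.0) - np.eye(30) * 0.8)
        r = optimize_resolution([(protein.structure, pae,
                                  [range(1, 31)])])
        assert r == 1.0

    def test_weakly_coupled_halves_force_lower_resolution(self):
        protein = make_structure(FixtureSpec(seed=9, residues_per_module=40))
        values = np.full((40, 40), 4.8)   # weak cross edges, still below 5 A
        values[:20, :20] = 1.0
        values[20:, 20:] = 1.0
        np.fill_diagonal(values, 0.2)
        pae = PAEMatrix(values)
        cases = [(protein.structure, pae, [range(1, 41)])]
        r = optimize_resolution(cases)
        assert r < 1.0
        # returned value honours the no-split constraint
        graph = build_pae_graph(protein.structure, pae)
        partition = detect_communities(graph, resolution=r)
        owners = {tuple(sorted(c)) for c in partition
                  if set(range(1, 41)) & set(c)}
        assert len(owners) == 1
        # and is the first such value on the downward scan
        above = round(r + 0.01, 10)
        if above <= 1.0:
            partition = detect_communities(graph, resolution=above)
            owners = {id(c) for c in partition for i in range(1, 41) if i in c}
            assert len(owners) > 1

    def test_empty_collection_is_error(self):
        with pytest.raises(ValueError):
            optimize_resolution([])
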