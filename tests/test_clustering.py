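"""Prune / label / refine / components and the end-to-end pipeline."""

import io

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cassnet.clustering import (
    Params,
    cass_cluster,
    connected_components,
    label_cores,
    prune_by_epsilon,
    refine_edges,
)
from cassnet.errors import ConsistencyError, ParameterError
from cassnet.similarity import compute_all_similarities
from cassnet.graph_io import (
    Graph,
    WeightedEdgeTable,
    read_similarity_cache,
    write_similarity_cache,
)
from cassnet.synth import erdos_renyi_graph, planted_partition_graph


class UnionFind:
    """Independent component oracle."""

    def __init__(self, nodes):
        self.parent = {v: v for v in nodes}

    def find(self, v):
        while self.parent[v] != v:
            self.parent[v] = self.parent[self.parent[v]]
            v = self.parent[v]
        return v

    def union(self, u, v):
        ru, rv = self.find(u), self.find(v)
        if ru != rv:
            self.parent[ru] = rv


def union_find_components(g: Graph):
    uf = UnionFind(g.nodes)
    for u, v in g.edges:
        uf.union(u, v)
    comps = {}
    for v in g.nodes:
        comps.setdefault(uf.find(v), set()).add(v)
    return {frozenset(c) for c in comps.values()}


edge_list_st = st.lists(
    st.tuples(st.integers(0, 30), st.integers(0, 30)).filter(lambda e: e[0] != e[1]),
    max_size=70,
)


class TestPrune:
    def test_threshold_below_everything_keeps_graph(self, toys):
        g = toys["k4"].graph
        table = WeightedEdgeTable({e: 1.0 for e in g.edges})
        assert prune_by_epsilon(table, g, 0.7).edges == g.edges

    def test_two_k4_bridge_removed_at_0_6(self, two_k4):
        table = WeightedEdgeTable(two_k4.expected_similarities)
        pruned = prune_by_epsilon(table, two_k4.graph, 0.6)
        assert (3, 4) not in pruned.edges
        assert pruned.number_of_edges == 12
        assert pruned.nodes == two_k4.graph.nodes  # node set unchanged

    def test_epsilon_one_keeps_only_identical_neighborhoods(self, toys):
        fx = toys["path_3"]
        table = WeightedEdgeTable(fx.expected_similarities)
        assert prune_by_epsilon(table, fx.graph, 1.0).number_of_edges == 0

    def test_edges_at_exactly_epsilon_survive(self):
        g = Graph(edges=[(0, 1)])
        table = WeightedEdgeTable({(0, 1): 0.5})
        assert prune_by_epsilon(table, g, 0.5).edges == {(0, 1)}

    def test_missing_edge_is_consistency_error(self, toys):
        with pytest.raises(ConsistencyError):
            prune_by_epsilon(WeightedEdgeTable(), toys["k3"].graph, 0.5)

    @pytest.mark.parametrize("eps", [0.0, -0.1, 1.3])
    def test_epsilon_range(self, toys, eps):
        g = toys["k3"].graph
        table = WeightedEdgeTable({e: 1.0 for e in g.edges})
        with pytest.raises(ParameterError):
            prune_by_epsilon(table, g, eps)


class TestLabelCores:
    def test_star_center_only(self):
        g = Graph(edges=[(0, 1), (0, 2), (0, 3)])
        labeling = label_cores(g, 2)
        assert labeling.cores == {0}
        assert not labeling.is_core(1)

    def test_m_above_max_degree_gives_no_cores(self, toys):
        g = toys["k4"].graph
        assert label_cores(g, 10).cores == set()

    def test_two_k4_all_core_after_pruning(self, two_k4):
        table = WeightedEdgeTable(two_k4.expected_similarities)
        pruned = prune_by_epsilon(table, two_k4.graph, 0.6)
        assert label_cores(pruned, 2).cores == set(range(8))

    def test_strict_mode_uses_greater_than(self):
        g = Graph(edges=[(0, 1), (0, 2)])  # center degree exactly 2
        assert label_cores(g, 2).cores == {0}
        assert label_cores(g, 2, strict=True).cores == set()

    def test_count_self_shifts_threshold(self):
        g = Graph(edges=[(0, 1)])  # degrees 1; closed neighborhood size 2
        assert label_cores(g, 2).cores == set()
        assert label_cores(g, 2, count_self=True).cores == {0, 1}


class TestRefineEdges:
    def test_all_non_core_empties_graph(self, toys):
        g = toys["cycle_4"].graph
        labeling = label_cores(g, 3)  # every degree is 2
        assert refine_edges(g, labeling).number_of_edges == 0

    def test_all_core_keeps_everything(self, toys):
        g = toys["k4"].graph
        labeling = label_cores(g, 2)
        assert refine_edges(g, labeling).edges == g.edges

    def test_only_non_core_non_core_edges_dropped(self):
        g = Graph(edges=[(1, 2), (2, 3), (3, 4)])
        labeling = label_cores(g, 2)  # cores: 2 and 3
        labeling.cores.discard(3)  # force 3 non-core: (3,4) must go
        refined = refine_edges(g, labeling)
        assert refined.edges == {(1, 2), (2, 3)}


class TestConnectedComponents:
    def test_component_with_node_zero_gets_id_zero(self, toys):
        clustering = connected_components(toys["two_components"].graph)
        assert clustering.clusters == {0: {0, 1, 2, 3}, 5: {5, 6, 7, 8}}
        assert clustering.unassigned == {4}

    def test_no_edges_means_all_unassigned(self):
        g = Graph(nodes=range(5))
        clustering = connected_components(g)
        assert clustering.n_clusters == 0
        assert clustering.unassigned == set(range(5))

    def test_small_example(self):
        g = Graph(edges=[(7, 8), (1, 2), (2, 3)])
        clustering = connected_components(g)
        assert clustering.clusters == {1: {1, 2, 3}, 7: {7, 8}}

    def test_long_path_converges(self):
        # worst case for label propagation: a path keyed against the flow
        g = Graph(edges=[(i, i + 1) for i in range(99)])
        clustering = connected_components(g)
        assert clustering.clusters == {0: set(range(100))}

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(edge_list_st)
    def test_matches_union_find_oracle(self, raw):
        g = Graph(edges=raw)
        clustering = connected_components(g)
        clustering.validate()
        oracle = {c for c in union_find_components(g) if len(c) >= 2}
        assert {frozenset(c) for c in clustering.clusters.values()} == oracle
        # cross-check with networkx as a second independent oracle
        G = nx.Graph(g.edges)
        G.add_nodes_from(g.nodes)
        nx_comps = {frozenset(c) for c in nx.connected_components(G) if len(c) >= 2}
        assert {frozenset(c) for c in clustering.clusters.values()} == nx_comps


class TestParams:
    @pytest.mark.parametrize("eps,m", [(0.0, 2), (1.5, 2), (0.5, 1), (0.5, 2.5)])
    def test_invalid_rejected(self, eps, m):
        with pytest.raises(ParameterError):
            Params(eps, m)


class TestPipeline:
    def test_two_k4_toy_end_to_end(self, two_k4):
        clustering, table, stats = cass_cluster(
            two_k4.graph, two_k4.edges, Params(0.6, 2)
        )
        assert clustering.clusters == two_k4.expected_clusters
        assert clustering.unassigned == set()
        assert stats is not None

    def test_m_above_max_degree_leaves_all_unassigned(self, toys):
        g = toys["k4"].graph
        clustering, _, _ = cass_cluster(g, params=Params(0.5, 10))
        assert clustering.n_clusters == 0
        assert clustering.unassigned == g.nodes

    def test_output_independent_of_flags_and_partitions(self):
        g = erdos_renyi_graph(80, 6, seed=17)
        ref, _, _ = cass_cluster(g, params=Params(0.5, 2), use_bloom=False)
        for bloom, direction, parts in [
            (True, "forward", 1),
            (True, "reverse", 5),
            (False, "reverse", 13),
        ]:
            got, _, _ = cass_cluster(
                g,
                params=Params(0.5, 2),
                use_bloom=bloom,
                direction=direction,
                partitions=parts,
            )
            assert got.clusters == ref.clusters
            assert got.unassigned == ref.unassigned

    def test_cache_reuse_gives_identical_clustering(self, tmp_path):
        g = erdos_renyi_graph(100, 8, seed=29)
        scratch, table, _ = cass_cluster(g, params=Params(0.4, 2))
        cache = tmp_path / "sims.tsv"
        write_similarity_cache(table, cache)
        reloaded = read_similarity_cache(cache)
        cached, _, stats = cass_cluster(
            g, params=Params(0.4, 2), similarity_table=reloaded
        )
        assert stats is None  # similarity stage skipped
        assert cached.clusters == scratch.clusters
        assert cached.unassigned == scratch.unassigned

    def test_no_edges_between_clusters_in_refined_graph(self):
        g, _ = planted_partition_graph(3, 10, 0.8, 0.05, seed=2)
        table, _ = compute_all_similarities(g)
        pruned = prune_by_epsilon(table, g, 0.4)
        labeling = label_cores(pruned, 2)
        refined = refine_edges(pruned, labeling)
        clustering = connected_components(refined)
        for u, v in refined.edges:
            cu = clustering.assignment.get(u)
            cv = clustering.assignment.get(v)
            assert cu == cv and cu is not None

    def test_every_cluster_anchored_on_a_core(self):
        g = erdos_renyi_graph(90, 7, seed=31)
        table, _ = compute_all_similarities(g)
        pruned = prune_by_epsilon(table, g, 0.45)
        labeling = label_cores(pruned, 2)
        refined = refine_edges(pruned, labeling)
        clustering = connected_components(refined)
        for members in clustering.clusters.values():
            assert members & labeling.cores
            for v in members - labeling.cores:
                assert refined.neighbors(v) & labeling.cores


def assigned_nodes(g, table, eps, m):
    pruned = prune_by_epsilon(table, g, eps)
    labeling = label_cores(pruned, m)
    refined = refine_edges(pruned, labeling)
    return (
        pruned.edges,
        labeling.cores,
        refined.edges,
        set(connected_components(refined).assignment),
    )


class TestMonotonicity:
    @pytest.mark.parametrize("seed", [1, 8, 23])
    def test_everything_shrinks_as_epsilon_grows(self, seed):
        g = erdos_renyi_graph(90, 8, seed=seed)
        table, _ = compute_all_similarities(g)
        stages = [assigned_nodes(g, table, eps, 2) for eps in (0.2, 0.4, 0.6, 0.8)]
        for lo, hi in zip(stages, stages[1:]):
            for coarse, fine in zip(hi, lo):
                assert coarse <= fine

    @pytest.mark.parametrize("seed", [4, 15])
    def test_cores_and_assignment_shrink_as_m_grows(self, seed):
        g, _ = planted_partition_graph(4, 15, 0.6, 0.02, seed=seed)
        table, _ = compute_all_similarities(g)
        prev = None
        for m in (2, 3, 4, 5):
            _, cores, _, assigned = assigned_nodes(g, table, 0.3, m)
            if prev is not None:
                assert cores <= prev[0]
                assert assigned <= prev[1]
            prev = (cores, assigned)
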