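import numpy as np
import pytest

from mirprio.errors import RowError
from mirprio.interaction_network import (
    ExpansionKind, NetworkMode, ScoredEdge, build_network,
    connected_components, filter_edges, parse_edge_table,
)
from mirprio.target_catalog import build_catalog


def brute_force_components(nodes, edges):
    """Independent union-find oracle over an undirected edge list."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted((frozenset(g) for g in groups.values()), key=sorted)


class TestParseEdgeTable:
    def test_canonical_dedup_keeps_max_score(self):
        edges = parse_edge_table("geneA\tgeneB\tscore\nA\tB\t950\nB\tA\t900\n")
        assert edges == [ScoredEdge("A", "B", 950)]

    def test_self_loop_dropped(self, caplog):
        edges = parse_edge_table("geneA\tgeneB\tscore\nA\tA\t999\nA\tB\t950\n")
        assert edges == [ScoredEdge("A", "B", 950)]

    def test_out_of_range_score_is_row_error(self):
        with pytest.raises(RowError):
            parse_edge_table("geneA\tgeneB\tscore\nA\tB\t1500\n")

    def test_headerless_string_links_style(self):
        edges = parse_edge_table("A B 950\nB C 920\n")
        assert edges == [ScoredEdge("A", "B", 950), ScoredEdge("B", "C", 920)]

    def test_strict_alias_map(self):
        amap = {"ENSP1": "A", "ENSP2": "B"}
        edges = parse_edge_table("geneA\tgeneB\tscore\nENSP1\tENSP2\t950\n",
                                 alias_map=amap)
        assert edges == [ScoredEdge("A", "B", 950)]
        with pytest.raises(RowError):
            parse_edge_table("geneA\tgeneB\tscore\nENSP9\tENSP2\t950\n",
                             alias_map=amap, strict_aliases=True)


class TestFilterEdges:
    def test_boundary_is_inclusive(self):
        edges = [ScoredEdge("A", "B", 899), ScoredEdge("A", "C", 900),
                 ScoredEdge("A", "D", 901)]
        assert {e.combined_score for e in filter_edges(edges, 900)} == {900, 901}

    def test_zero_threshold_is_identity(self):
        edges = [ScoredEdge("A", "B", 5)]
        assert filter_edges(edges, 0) == edges
        assert filter_edges([], 900) == []

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(5)
        edges = [ScoredEdge(f"A{i}", f"B{i}", int(s))
                 for i, s in enumerate(rng.integers(0, 1001, 50))]
        once = filter_edges(edges, 900)
        assert filter_edges(once, 900) == once
        assert set(filter_edges(edges, 950)) <= set(once)


class TestBuildNetwork:
    def _catalog(self):
        return build_catalog({"A", "C"}, {"B"})

    def test_cross_group_excludes_within_group(self):
        edges = [ScoredEdge("A", "B", 950), ScoredEdge("A", "C", 950)]
        cross = build_network(self._catalog(), edges, NetworkMode.CROSS_GROUP)
        expanded = build_network(self._catalog(), edges, NetworkMode.EXPANDED)
        assert [(e.a, e.b) for e in cross.edges] == [("A", "B")]
        assert len(expanded.edges) == 2

    def test_both_label_counts_as_either_side(self):
        catalog = build_catalog({"A", "B"}, {"B"})  # B is BOTH
        cross = build_network(catalog, [ScoredEdge("A", "B", 950)],
                              NetworkMode.CROSS_GROUP)
        assert len(cross.edges) == 1

    def test_non_catalog_endpoint_dropped(self):
        cross = build_network(self._catalog(), [ScoredEdge("A", "Z", 950)],
                              NetworkMode.CROSS_GROUP)
        assert cross.edges == []

    def test_predicted_only_expansion_excludes_validated_pairs(self):
        catalog = build_catalog({"A", "C"}, {"B", "D"})
        edges = [ScoredEdge("A", "C", 950), ScoredEdge("B", "D", 950)]
        expanded = build_network(catalog, edges, NetworkMode.EXPANDED,
                                 expansion=ExpansionKind.PREDICTED_ONLY)
        assert [(e.a, e.b) for e in expanded.edges] == [("A", "C")]


class TestConnectedComponents:
    def test_isolated_node_excluded(self):
        catalog = build_catalog({"A", "C", "E"}, {"B", "D"})
        net = build_network(catalog, [ScoredEdge("A", "B", 950),
                                      ScoredEdge("C", "D", 950)],
                            NetworkMode.CROSS_GROUP)
        comps, isolated = connected_components(net)
        assert [c.genes for c in comps] == [("A", "B"), ("C", "D")]
        assert isolated == {"E"}

    def test_path_is_one_component(self):
        catalog = build_catalog({"A", "C"}, {"B"})
        net = build_network(catalog, [ScoredEdge("A", "B", 950),
                                      ScoredEdge("B", "C", 950)],
                            NetworkMode.CROSS_GROUP)
        comps, _ = connected_components(net)
        assert [c.genes for c in comps] == [("A", "B", "C")]

    def test_two_planted_modules_recovered(self):
        """12-node fixture with two planted modules matches the union-find oracle."""
        preds = {f"P{i}" for i in range(6)}
        vals = {f"V{i}" for i in range(6)}
        catalog = build_catalog(preds, vals)
        edge_list = [(f"P{i}", f"V{i}") for i in range(6)]
        edge_list += [(f"V{i}", f"P{i + 1}") for i in range(2)]   # module 1: P0..P2
        edge_list += [(f"V{i}", f"P{i + 1}") for i in range(3, 5)]  # module 2
        edges = [ScoredEdge(*sorted(e), 950) for e in edge_list]
        net = build_network(catalog, edges, NetworkMode.CROSS_GROUP)
        comps, _ = connected_components(net)
        oracle = brute_force_components(preds | vals,
                                        [(e.a, e.b) for e in edges])
        oracle = [g for g in oracle if len(g) >= 2]
        assert sorted((c.gene_set() for c in comps), key=sorted) == oracle
        assert len(comps) == 2

    def test_matches_oracle_on_random_small_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 11))
            nodes = [f"N{i}" for i in range(n)]
            preds = set(nodes[: n // 2]) or {nodes[0]}
            vals = set(nodes) - preds or {nodes[-1]}
            catalog = build_catalog(preds, vals)
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.25:
                        edges.append(ScoredEdge(nodes[i], nodes[j], 950))
            net = build_network(catalog, edges, NetworkMode.EXPANDED)
            comps, isolated = connected_components(net, min_component_size=1)
            oracle = brute_force_components(set(nodes),
                                            [(e.a, e.b) for e in net.edges])
            assert sorted((c.gene_set() for c in comps), key=sorted) == oracle
            assert not isolated
            # partition invariant
            seen = [g for c in comps for g in c.genes]
            assert sorted(seen) == sorted(nodes)


def test_coarsening_cross_components_nest_in_expanded():
    """Every cross-group component sits inside exactly one expanded component."""
    rng = np.random.default_rng(23)
    for _ in range(300):
        n = int(rng.integers(3, 12))
        nodes = [f"N{i}" for i in range(n)]
        preds = {x for x in nodes if rng.random() < 0.5} or {nodes[0]}
        vals = (set(nodes) - preds) or {nodes[-1]}
        if rng.random() < 0.3:  # occasionally overlap -> BOTH labels
            vals = vals | {nodes[0]}
        catalog = build_catalog(preds, vals)
        edges = [ScoredEdge(nodes[i], nodes[j], 950)
                 for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.3]
        cross = build_network(catalog, edges, NetworkMode.CROSS_GROUP)
        expanded = build_network(catalog, edges, NetworkMode.EXPANDED)
        assert set(cross.edges) <= set(expanded.edges)
        ccomps, _ = connected_components(cross, 1)
        ecomps, _ = connected_components(expanded, 1)
        for cc in ccomps:
            containers = [ec for ec in ecomps if cc.gene_set() <= ec.gene_set()]
            assert len(containers) == 1
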