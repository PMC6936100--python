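"""Graph construction, shortest paths, betweenness, MST, pathway weights."""

import networkx as nx
import numpy as np
import pytest

import comorbnet as cn
from comorbnet.network import EdgeListParseError

from conftest import (
    brute_force_mst_weight,
    enumerate_all_shortest_paths,
    enumerate_simple_path_distance,
    random_connected_graph,
)


class TestReadEdgeList:
    def test_deduplicates_reversed_pairs(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a b\nb a\nb c\n")
        g = cn.read_edge_list(p)
        assert sorted(g.nodes) == ["a", "b", "c"]
        assert g.number_of_edges() == 2

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        g = cn.read_edge_list(p)
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_self_loop_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "e.tsv"
        p.write_text("a a\na b\n")
        with caplog.at_level("WARNING"):
            g = cn.read_edge_list(p)
        assert g.number_of_edges() == 1
        assert "self-loop" in caplog.text

    def test_row_order_irrelevant_and_comments_skipped(self, tmp_path):
        p1, p2 = tmp_path / "e1.tsv", tmp_path / "e2.tsv"
        p1.write_text("# comment\na b\nb c\n")
        p2.write_text("b c\na b\n")
        g1, g2 = cn.read_edge_list(p1), cn.read_edge_list(p2)
        norm = lambda g: sorted(tuple(sorted(e)) for e in g.edges)
        assert norm(g1) == norm(g2)

    @pytest.mark.parametrize("content,msg", [
        ("a\n", "line 1"),
        ("a b x\n", "line 1"),
        ("a b -2\n", "line 1"),
    ])
    def test_malformed_rows_name_line(self, tmp_path, content, msg):
        p = tmp_path / "e.tsv"
        p.write_text(content)
        with pytest.raises(EdgeListParseError, match=msg):
            cn.read_edge_list(p, weighted=True)

    def test_weighted_roundtrip(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a b 0.25\nb c 2\n")
        g = cn.read_edge_list(p, weighted=True)
        assert g.edges["a", "b"]["weight"] == 0.25
        out = tmp_path / "out.tsv"
        cn.write_edge_list(g, out, weighted=True)
        g2 = cn.read_edge_list(out, weighted=True)
        assert g2.edges["b", "c"]["weight"] == 2.0


class TestLargestComponent:
    def test_picks_largest(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
                      ("x", "y"), ("y", "z")])
        lcc = cn.largest_connected_component(g)
        assert sorted(lcc.nodes) == ["a", "b", "c", "d", "e"]

    def test_connected_graph_is_identity(self, path3):
        lcc = cn.largest_connected_component(path3)
        assert sorted(lcc.nodes) == sorted(path3.nodes)
        assert sorted(lcc.edges) == sorted(path3.edges)

    def test_tie_broken_lexicographically(self):
        g = nx.Graph([("x", "y"), ("a", "b")])
        assert sorted(cn.largest_connected_component(g).nodes) == ["a", "b"]

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            cn.largest_connected_component(nx.Graph())


class TestShortestPaths:
    def test_path_graph_hops(self, path3):
        d = cn.all_pairs_shortest_paths(path3)
        assert d.loc("a", "c") == 2.0

    def test_weighted_triangle_detour(self, weighted_triangle):
        d = cn.all_pairs_shortest_paths(weighted_triangle, use_weights=True)
        assert d.loc("a", "c") == 2.0  # a-b-c beats the direct weight-10 edge

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("a")
        d = cn.all_pairs_shortest_paths(g)
        assert d.values.shape == (1, 1) and d.values[0, 0] == 0.0

    def test_disconnected_errors(self):
        g = nx.Graph([("a", "b"), ("x", "y")])
        with pytest.raises(ValueError, match="largest_connected_component"):
            cn.all_pairs_shortest_paths(g)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_simple_path_enumeration(self, weighted):
        rng = np.random.default_rng(42)
        for _ in range(100):
            g = random_connected_graph(rng, n_max=7, weighted=weighted)
            d = cn.all_pairs_shortest_paths(g, use_weights=weighted)
            nodes = sorted(g.nodes)
            s, t = nodes[rng.integers(len(nodes))], nodes[rng.integers(len(nodes))]
            expect = enumerate_simple_path_distance(g, s, t, use_weights=weighted)
            assert d.loc(s, t) == pytest.approx(expect)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_connected_graph(rng, n_max=7, weighted=True)
            d = cn.all_pairs_shortest_paths(g, use_weights=True).values
            n = d.shape[0]
            for i in range(n):
                for j in range(n):
                    assert np.all(d[i, j] <= d[i, :] + d[:, j] + 1e-12)


class TestBetweenness:
    def test_path_center(self, path3):
        c = cn.betweenness(path3)
        assert c == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_center(self):
        g = nx.star_graph(3)
        g = nx.relabel_nodes(g, {0: "h", 1: "l1", 2: "l2", 3: "l3"})
        c = cn.betweenness(g)
        assert c["h"] == 3.0
        assert all(c[v] == 0.0 for v in ("l1", "l2", "l3"))

    def test_matches_exhaustive_shortest_path_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            g = random_connected_graph(rng, n_max=8)
            got = cn.betweenness(g)
            nodes = sorted(g.nodes)
            expect = {v: 0.0 for v in nodes}
            for i, s in enumerate(nodes):
                for t in nodes[i + 1:]:
                    paths = enumerate_all_shortest_paths(g, s, t)
                    for v in nodes:
                        if v in (s, t):
                            continue
                        through = sum(1 for p in paths if v in p)
                        expect[v] += through / len(paths)
            for v in nodes:
                assert got[v] == pytest.approx(expect[v], abs=1e-9)


class TestAverageDegree:
    def test_path_subset(self, path3):
        assert cn.average_degree(path3, {"a", "b"}) == 1.5

    def test_star_center_and_leaf(self):
        g = nx.relabel_nodes(nx.star_graph(3), {0: "h", 1: "x", 2: "y", 3: "z"})
        assert cn.average_degree(g, {"h", "x"}) == 2.0

    def test_empty_set_errors(self, path3):
        with pytest.raises(ValueError):
            cn.average_degree(path3, set())


class TestMinimumSpanningTree:
    def test_weighted_triangle(self, weighted_triangle):
        t = cn.minimum_spanning_tree(weighted_triangle)
        assert sorted(tuple(sorted(e)) for e in t.edges) == [("a", "b"), ("b", "c")]

    def test_tree_input_is_identity(self, path3):
        t = cn.minimum_spanning_tree(path3)
        assert sorted(t.edges) == sorted(path3.edges)

    def test_edge_count(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            g = random_connected_graph(rng, n_max=7, weighted=True)
            t = cn.minimum_spanning_tree(g)
            assert t.number_of_edges() == g.number_of_nodes() - 1

    def test_total_weight_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            g = random_connected_graph(rng, n_max=7, weighted=True)
            t = cn.minimum_spanning_tree(g)
            total = sum(w for _, _, w in t.edges(data="weight"))
            assert total == pytest.approx(brute_force_mst_weight(g))


class TestPathwayEdgeWeights:
    def test_weight_formula(self, path3):
        ann = {"p1": {"a", "b"}, "p2": {"a", "b"}, "p3": {"a", "b"},
               "p4": {"b", "c", "zzz"}}
        w = cn.pathway_edge_weights(path3, ann)
        assert w.edges["a", "b"]["weight"] == pytest.approx(0.25)
        assert w.edges["b", "c"]["weight"] == pytest.approx(0.5)

    def test_unannotated_edge_keeps_unit_weight(self, path3):
        w = cn.pathway_edge_weights(path3, {})
        assert w.edges["a", "b"]["weight"] == 1.0

    def test_monotone_decreasing_in_frequency(self, path3):
        ann = {f"p{i}": {"a", "b"} for i in range(5)}
        ann["q"] = {"b", "c"}
        w = cn.pathway_edge_weights(path3, ann)
        assert w.edges["a", "b"]["weight"] < w.edges["b", "c"]["weight"]

    def test_uniform_annotation_preserves_mst(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            g = random_connected_graph(rng, n_max=7)
            # every edge's endpoints co-occur in the same single pathway
            ann = {"all": set(g.nodes)}
            w = cn.pathway_edge_weights(g, ann)
            t0 = sorted(tuple(sorted(e)) for e in cn.minimum_spanning_tree(g).edges)
            t1 = sorted(tuple(sorted(e)) for e in cn.minimum_spanning_tree(w).edges)
            assert t0 == t1


class TestGmt:
    def test_roundtrip(self, tmp_path):
        ann = {"P1": {"a", "b"}, "P2": {"c"}}
        p = tmp_path / "p.gmt"
        cn.write_gmt(ann, p)
        assert cn.read_gmt(p) == ann

    def test_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "p.gmt"
        p.write_text("P1\tna\ta\nP1\tna\tb\n")
        with pytest.raises(EdgeListParseError, match="duplicate"):
            cn.read_gmt(p)
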