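import io
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motifspace.graph_core import (
    DegreePair,
    DirectedGraph,
    EdgeListError,
    degree_pair,
    incidence_matrix,
    induced_subgraph,
    is_weakly_connected,
    parse_edge_list,
    read_edge_list,
    write_edge_list,
)

from .conftest import graph_from_text


class TestParseEdgeList:
    def test_basic(self):
        g = graph_from_text("1 2\n2 3\n")
        assert g.vertices == ("1", "2", "3")
        assert g.edges == (("1", "2"), ("2", "3"))

    def test_duplicate_collapses_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            g = graph_from_text("a b\na b\n")
        assert g.n_edges == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_self_loop_is_hard_error_with_line_number(self):
        with pytest.raises(EdgeListError, match="self-loop at line 1"):
            graph_from_text("x x\n")

    def test_self_loop_later_line(self):
        with pytest.raises(EdgeListError, match="line 3"):
            graph_from_text("a b\n\nc c\n")

    def test_short_line_rejected(self):
        with pytest.raises(EdgeListError, match="line 2"):
            graph_from_text("a b\nc\n")

    def test_comments_blanks_and_extra_tokens(self, caplog):
        with caplog.at_level(logging.INFO, logger="motifspace.graph_core"):
            g = graph_from_text("# header\n\na b 1.5 activator\nb c\n")
        assert g.edges == (("a", "b"), ("b", "c"))
        assert any("extra token" in r.message for r in caplog.records)

    def test_custom_delimiter_and_comment(self):
        g = parse_edge_list(["% note", "a,b", "b,c"], comment_prefix="%", delimiter=",")
        assert g.edges == (("a", "b"), ("b", "c"))

    def test_read_from_stream_and_path(self, tmp_path):
        p = tmp_path / "g.txt"
        p.write_text("1 2\n2 3\n")
        assert read_edge_list(p).edges == read_edge_list(io.StringIO("1 2\n2 3\n")).edges


class TestDirectedGraph:
    def test_rejects_self_loop(self):
        with pytest.raises(ValueError, match="self-loop"):
            DirectedGraph(edges=[("u", "u")])

    def test_rejects_duplicate_edge(self):
        with pytest.raises(ValueError, match="duplicate"):
            DirectedGraph(edges=[("u", "v"), ("u", "v")])

    def test_antiparallel_pair_allowed(self):
        g = DirectedGraph(edges=[("u", "v"), ("v", "u")])
        assert g.n_edges == 2

    def test_first_appearance_order(self):
        g = graph_from_text("b a\nc b\n")
        assert g.vertices == ("b", "a", "c")
        assert [g.index(v) for v in g.vertices] == [0, 1, 2]

    def test_unknown_vertex(self):
        g = graph_from_text("a b\n")
        with pytest.raises(KeyError):
            g.index("zzz")


class TestIncidenceMatrix:
    def test_paper_normalized_matrix(self):
        g = graph_from_text("1 3\n3 2\n2 4\n4 1\n")
        m = incidence_matrix(
            g,
            vertex_order=("1", "3", "2", "4"),
            edge_order=(("1", "3"), ("3", "2"), ("2", "4"), ("4", "1")),
        )
        assert m.entries.tolist() == [
            [1, 0, 0, -1],
            [-1, 1, 0, 0],
            [0, -1, 1, 0],
            [0, 0, -1, 1],
        ]

    def test_single_edge(self):
        g = graph_from_text("u v\n")
        m = incidence_matrix(g)
        assert m.entries.tolist() == [[1], [-1]]

    def test_default_orders(self, fig4_graph):
        m = incidence_matrix(fig4_graph)
        assert m.row_labels == fig4_graph.vertices
        assert m.col_labels == fig4_graph.edges

    def test_column_invariant_and_zero_sum(self, fig4_graph):
        m = incidence_matrix(fig4_graph)
        a = m.entries
        assert (a.sum(axis=0) == 0).all()
        assert int(a.sum()) == 0
        assert (a == 1).sum() == (a == -1).sum() == fig4_graph.n_edges

    def test_bad_orders_rejected(self, fig4_graph):
        with pytest.raises(ValueError, match="permutation"):
            incidence_matrix(fig4_graph, vertex_order=("1", "2"))
        with pytest.raises(ValueError, match="permutation"):
            incidence_matrix(fig4_graph, edge_order=((("2", "1"),) * 6))


class TestInducedSubgraph:
    def test_four_cycle_drop_one_vertex(self, cycle):
        # brute force over the 4 subsets: each is a 2-edge directed path
        g = cycle(4)
        for drop in g.vertices:
            keep = [v for v in g.vertices if v != drop]
            sub = induced_subgraph(g, keep)
            assert sub.n_vertices == 3 and sub.n_edges == 2
            degs = sorted((sub.degree_pair(v).d_in, sub.degree_pair(v).d_out) for v in keep)
            assert degs == [(0, 1), (1, 0), (1, 1)]

    def test_identity(self, fig4_graph):
        sub = induced_subgraph(fig4_graph, fig4_graph.vertices)
        assert sub == fig4_graph

    def test_single_vertex(self, fig4_graph):
        sub = induced_subgraph(fig4_graph, ["5"])
        assert sub.vertices == ("5",) and sub.n_edges == 0

    def test_unknown_vertex(self, fig4_graph):
        with pytest.raises(KeyError):
            induced_subgraph(fig4_graph, ["5", "nope"])


class TestDegreePair:
    def test_cycle(self, cycle):
        g = cycle(3)
        assert all(degree_pair(g, v) == DegreePair(1, 1) for v in g.vertices)

    def test_star_hub(self, star_graph):
        assert degree_pair(star_graph, "h") == DegreePair(0, 3)

    def test_fig4_node2(self, fig4_graph):
        assert degree_pair(fig4_graph, "2") == DegreePair(d_in=1, d_out=2)

    def test_degree_sums_equal_edge_count(self, fig4_graph):
        din = sum(fig4_graph.degree_pair(v).d_in for v in fig4_graph.vertices)
        dout = sum(fig4_graph.degree_pair(v).d_out for v in fig4_graph.vertices)
        assert din == dout == fig4_graph.n_edges


class TestWeakConnectivity:
    def test_cycle_connected(self, cycle):
        assert is_weakly_connected(cycle(3))

    def test_disjoint_edges(self):
        assert not is_weakly_connected(graph_from_text("a b\nc d\n"))

    def test_direction_ignored(self):
        assert is_weakly_connected(graph_from_text("1 2\n3 2\n"))

    def test_single_vertex(self):
        g = DirectedGraph(vertices=["x"])
        assert is_weakly_connected(g)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            is_weakly_connected(DirectedGraph())


edge_lists = st.lists(
    st.tuples(st.integers(0, 7), st.integers(0, 7)).filter(lambda e: e[0] != e[1]),
    min_size=1,
    max_size=20,
    unique=True,
).map(lambda es: [(f"n{u}", f"n{v}") for u, v in es])


@given(edge_lists)
@settings(max_examples=100, deadline=None)
def test_write_read_round_trip(edges):
    g = DirectedGraph(edges=edges)
    back = parse_edge_list(write_edge_list(g).splitlines())
    assert set(back.vertices) == set(g.vertices)
    assert set(back.edges) == set(g.edges)


@given(edge_lists)
@settings(max_examples=100, deadline=None)
def test_incidence_counts_property(edges):
    g = DirectedGraph(edges=edges)
    a = incidence_matrix(g).entries
    assert (a == 1).sum() == (a == -1).sum() == g.n_edges
    assert int(a.sum()) == 0


@given(edge_lists)
@settings(max_examples=100, deadline=None)
def test_degree_sum_property(edges):
    g = DirectedGraph(edges=edges)
    assert sum(g.degree_pair(v).d_in for v in g.vertices) == g.n_edges
    assert sum(g.degree_pair(v).d_out for v in g.vertices) == g.n_edges
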