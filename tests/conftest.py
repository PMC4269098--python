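import pytest

from motifspace.graph_core import DirectedGraph, parse_edge_list


def graph_from_text(text: str) -> DirectedGraph:
    return parse_edge_list(text.splitlines())


@pytest.fixture
def fig4_graph() -> DirectedGraph:
    """Five-vertex example with twin pairs {2,4} and {1,3}."""
    return graph_from_text("2 1\n2 3\n4 1\n4 3\n5 2\n5 4\n")


@pytest.fixture
def star_graph() -> DirectedGraph:
    """Out-star hub -> {a, b, c}."""
    return graph_from_text("h a\nh b\nh c\n")


@pytest.fixture
def cycle():
    """Factory: directed n-cycle 1 -> 2 -> ... -> n -> 1."""

    def make(n: int) -> DirectedGraph:
        labels = [str(i + 1) for i in range(n)]
        return DirectedGraph(
            vertices=labels,
            edges=[(labels[i], labels[(i + 1) % n]) for i in range(n)],
        )

    return make


@pytest.fixture
def ffl() -> DirectedGraph:
    return graph_from_text("a b\na c\nb c\n")
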