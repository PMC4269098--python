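"""Directed-graph data model, plain-text edge-list I/O, and incidence matrices.

The whole toolchain operates on simple labeled digraphs: no self-loops, no
duplicate edges, but a pair of antiparallel edges ``(u, v)`` / ``(v, u)`` is
allowed.  Vertex order is the order of first appearance in the input; every
tie-break downstream (class representatives, enumeration order, report rows)
is resolved by that order, which makes all outputs deterministic across
processes regardless of hash randomization.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DegreePair",
    "DirectedGraph",
    "EdgeListError",
    "IncidenceMatrix",
    "degree_pair",
    "incidence_matrix",
    "induced_subgraph",
    "is_weakly_connected",
    "parse_edge_list",
    "read_edge_list",
    "write_edge_list",
]


class EdgeListError(ValueError):
    """Raised for malformed edge-list input (self-loops, short lines)."""


@dataclass(frozen=True)
class DegreePair:
    """In-degree / out-degree of a vertex, the unit of the frequency partition."""

    d_in: int
    d_out: int

    def __iter__(self):
        return iter((self.d_in, self.d_out))


class DirectedGraph:
    """Simple labeled digraph with stable first-appearance vertex order.

    Parameters
    ----------
    vertices:
        Optional iterable of vertex labels; establishes initial order.
    edges:
        Iterable of ``(source, target)`` label pairs.  Unknown endpoints are
        added in encounter order.

    Raises
    ------
    ValueError
        On a self-loop or a duplicate edge.
    """

    __slots__ = ("_order", "_index", "_out", "_in", "_edges", "_edge_set")

    def __init__(
        self,
        vertices: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self._order: list[str] = []
        self._index: dict[str, int] = {}
        self._out: dict[str, set[str]] = {}
        self._in: dict[str, set[str]] = {}
        self._edges: list[tuple[str, str]] = []
        self._edge_set: set[tuple[str, str]] = set()
        for v in vertices:
            self.add_vertex(v)
        for u, v in edges:
            self.add_edge(u, v)

    # -- construction -------------------------------------------------

    def add_vertex(self, v: str) -> None:
        if v not in self._index:
            self._index[v] = len(self._order)
            self._order.append(v)
            self._out[v] = set()
            self._in[v] = set()

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop ({u!r}, {v!r}) is not representable")
        if (u, v) in self._edge_set:
            raise ValueError(f"duplicate edge ({u!r}, {v!r})")
        self.add_vertex(u)
        self.add_vertex(v)
        self._edges.append((u, v))
        self._edge_set.add((u, v))
        self._out[u].add(v)
        self._in[v].add(u)

    # -- queries ------------------------------------------------------

    @property
    def vertices(self) -> tuple[str, ...]:
        return tuple(self._order)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(self._edges)

    @property
    def n_vertices(self) -> int:
        return len(self._order)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, v: str) -> bool:
        return v in self._index

    def index(self, v: str) -> int:
        """Position of *v* in first-appearance order."""
        try:
            return self._index[v]
        except KeyError:
            raise KeyError(f"unknown vertex {v!r}") from None

    def has_edge(self, u: str, v: str) -> bool:
        return (u, v) in self._edge_set

    def out_neighbors(self, v: str) -> tuple[str, ...]:
        """Out-neighbors of *v*, sorted by vertex order (deterministic)."""
        self.index(v)
        return tuple(sorted(self._out[v], key=self._index.__getitem__))

    def in_neighbors(self, v: str) -> tuple[str, ...]:
        self.index(v)
        return tuple(sorted(self._in[v], key=self._index.__getitem__))

    def out_set(self, v: str) -> frozenset[str]:
        return frozenset(self._out[v])

    def in_set(self, v: str) -> frozenset[str]:
        return frozenset(self._in[v])

    def degree_pair(self, v: str) -> DegreePair:
        self.index(v)
        return DegreePair(d_in=len(self._in[v]), d_out=len(self._out[v]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return (
            set(self._order) == set(other._order)
            and self._edge_set == other._edge_set
        )

    def __hash__(self):  # mutable container semantics
        raise TypeError("DirectedGraph is unhashable")

    def __repr__(self) -> str:
        return f"DirectedGraph(n={self.n_vertices}, m={self.n_edges})"


@dataclass(frozen=True)
class IncidenceMatrix:
    """Vertices x edges matrix: +1 marks an edge's source row, -1 its target.

    Every column therefore has exactly one +1 and one -1, the algebraic sum
    of all entries is zero, and the number of +1 entries equals the number
    of -1 entries equals the number of edges.
    """

    entries: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=np.int8)
        object.__setattr__(self, "entries", a)
        if a.ndim != 2:
            raise ValueError("incidence matrix must be 2-dimensional")
        if a.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("entry shape does not match labels")
        self.validate()

    def validate(self) -> None:
        a = self.entries
        if not np.isin(a, (-1, 0, 1)).all():
            raise ValueError("entries must lie in {-1, 0, +1}")
        if a.size:
            if not ((a == 1).sum(axis=0) == 1).all() or not (
                (a == -1).sum(axis=0) == 1
            ).all():
                raise ValueError("each column needs exactly one +1 and one -1")
        assert int(a.sum()) == 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape  # type: ignore[return-value]


def incidence_matrix(
    g: DirectedGraph,
    vertex_order: Sequence[str] | None = None,
    edge_order: Sequence[tuple[str, str]] | None = None,
) -> IncidenceMatrix:
    """Build the incidence matrix of *g* under the given row/column orders.

    Defaults to the graph's own first-appearance vertex order and edge
    insertion order.  The orders must be permutations of the graph's
    vertex and edge sets.
    """
    vo = tuple(vertex_order) if vertex_order is not None else g.vertices
    eo = tuple(tuple(e) for e in edge_order) if edge_order is not None else g.edges
    if sorted(vo) != sorted(g.vertices) or len(set(vo)) != len(vo):
        raise ValueError("vertex_order is not a permutation of the vertices")
    if sorted(eo) != sorted(g.edges) or len(set(eo)) != len(eo):
        raise ValueError("edge_order is not a permutation of the edges")
    pos = {v: i for i, v in enumerate(vo)}
    a = np.zeros((len(vo), len(eo)), dtype=np.int8)
    for j, (u, v) in enumerate(eo):
        a[pos[u], j] = 1
        a[pos[v], j] = -1
    return IncidenceMatrix(entries=a, row_labels=vo, col_labels=eo)


def induced_subgraph(g: DirectedGraph, vertex_set: Iterable[str]) -> DirectedGraph:
    """Subgraph on *vertex_set* with every edge of *g* internal to it.

    Vertex and edge order are inherited from *g*.
    """
    vs = set(vertex_set)
    for v in vs:
        g.index(v)
    keep = [v for v in g.vertices if v in vs]
    edges = [(u, v) for (u, v) in g.edges if u in vs and v in vs]
    return DirectedGraph(vertices=keep, edges=edges)


def degree_pair(g: DirectedGraph, v: str) -> DegreePair:
    """Exact ``(d_in, d_out)`` of vertex *v*."""
    return g.degree_pair(v)


def is_weakly_connected(g: DirectedGraph) -> bool:
    """True iff the underlying undirected graph is connected.

    A single vertex counts as connected; the empty graph is an error.
    """
    if g.n_vertices == 0:
        raise ValueError("connectivity is undefined for the empty graph")
    start = g.vertices[0]
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in g.out_neighbors(v) + g.in_neighbors(v):
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return len(seen) == g.n_vertices


# -- edge-list I/O ----------------------------------------------------


def parse_edge_list(
    lines: Iterable[str],
    *,
    comment_prefix: str = "#",
    delimiter: str | None = None,
) -> DirectedGraph:
    """Parse edge-list lines into a :class:`DirectedGraph`.

    Each non-comment, non-blank line must hold at least two tokens:
    source and target.  Extra tokens (weights, annotations) are ignored
    with a logged note; duplicate edges collapse to one with a warning;
    a self-loop is a hard error naming the line number.
    """
    g = DirectedGraph()
    extra_noted = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith(comment_prefix):
            continue
        tokens = line.split(delimiter)
        if len(tokens) < 2:
            raise EdgeListError(
                f"line {lineno}: expected at least 2 tokens, got {len(tokens)}"
            )
        u, v = tokens[0], tokens[1]
        if len(tokens) > 2 and not extra_noted:
            logger.info(
                "line %d: ignoring %d extra token(s) beyond source/target",
                lineno,
                len(tokens) - 2,
            )
            extra_noted = True
        if u == v:
            raise EdgeListError(f"self-loop at line {lineno}")
        if g.has_edge(u, v):
            logger.warning("line %d: duplicate edge (%s, %s) collapsed", lineno, u, v)
            continue
        g.add_edge(u, v)
    return g


def read_edge_list(
    source: str | os.PathLike | IO[str],
    *,
    comment_prefix: str = "#",
    delimiter: str | None = None,
) -> DirectedGraph:
    """Read an edge list from a path or an open text stream."""
    if hasattr(source, "read"):
        return parse_edge_list(
            source, comment_prefix=comment_prefix, delimiter=delimiter
        )
    with open(source, "r", encoding="utf-8") as fh:
        return parse_edge_list(fh, comment_prefix=comment_prefix, delimiter=delimiter)


def write_edge_list(g: DirectedGraph, target: str | os.PathLike | IO[str] | None = None) -> str:
    """Serialize *g* as an edge list, one ``source<TAB>target`` per line.

    Edges are ordered by (source, target) vertex input order; LF endings.
    Isolated vertices cannot be expressed in this dialect and are dropped
    with a warning.  Returns the text; also writes it if *target* given.
    """
    isolated = [
        v for v in g.vertices if not g.out_neighbors(v) and not g.in_neighbors(v)
    ]
    if isolated:
        logger.warning(
            "%d isolated vertex(es) not representable in an edge list: %s",
            len(isolated),
            ", ".join(isolated[:5]),
        )
    ordered = sorted(g.edges, key=lambda e: (g.index(e[0]), g.index(e[1])))
    text = "".join(f"{u}\t{v}\n" for u, v in ordered)
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(text)
    return text
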