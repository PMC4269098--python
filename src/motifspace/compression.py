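"""Parity-node detection and search-space compression.

Two notions of interchangeable ("parity") vertices are supported:

* ``degree`` — the frequency partition: vertices grouped by exact
  ``(d_in, d_out)``.  Faithful to the coarse definition but count-unsafe:
  equal degrees do not guarantee that swapping two vertices preserves the
  topology.
* ``structural`` (default) — twin vertices: identical external in- and
  out-neighborhoods and uniform intra-class adjacency.  *False twins* have
  no edges among themselves; *true twins* are pairwise mutually connected.
  Exchanging two structural twins is a graph automorphism, so every
  subgraph census is invariant under the swap.

Compression keeps the minimum-input-order member of each class (the
representative), removes the rest (``g_p``) together with their incident
edges (``g_cv``), and records class multiplicities so that exact censuses
of the original graph can be recovered by weighted expansion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from math import comb
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

from .graph_core import DegreePair, DirectedGraph, induced_subgraph

if TYPE_CHECKING:  # pragma: no cover
    from .codec import Code
    from .enumeration import SubgraphCensus

__all__ = [
    "CompressedGraph",
    "MultiplicityCensus",
    "ParityClass",
    "TwinKind",
    "compress",
    "expand_census",
    "find_parity_classes",
]


class TwinKind(str, enum.Enum):
    FALSE_TWIN = "false_twin"  # no edges among members
    TRUE_TWIN = "true_twin"  # all ordered intra-class pairs connected


@dataclass(frozen=True)
class ParityClass:
    """A set of mutually interchangeable vertices.

    ``representative`` is always the member earliest in input order.
    Singleton classes carry an arbitrary (FALSE_TWIN) kind.
    """

    members: tuple[str, ...]
    representative: str
    degree: DegreePair
    twin_kind: TwinKind

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CompressedGraph:
    """The retained graph plus everything needed to undo the compression.

    ``g_r`` holds the representatives (and all singleton-class vertices)
    with the edges among them; ``g_p`` the removed vertices; ``g_cv`` the
    original edges touching a removed vertex.  Together they partition the
    original vertex and edge sets.
    """

    g_r: DirectedGraph
    g_p: tuple[str, ...]
    g_cv: tuple[tuple[str, str], ...]
    classes: tuple[ParityClass, ...]
    multiplicity: Mapping[str, int]
    original: DirectedGraph = field(repr=False)

    @property
    def n_removed(self) -> int:
        return len(self.g_p)


def _structural_classes(g: DirectedGraph) -> list[ParityClass]:
    """Greedy order-deterministic partition into twin classes.

    Vertices are scanned in input order; each unassigned vertex first
    gathers its false twins (equal open neighborhoods), then — failing a
    class of size >= 2 — its true twins (equal closed neighborhoods).
    Equal open neighborhoods imply no intra-class edges; equal closed
    neighborhoods imply full mutual connection, so intra-class adjacency
    is automatically uniform.
    """
    open_key = {
        v: (g.out_set(v), g.in_set(v)) for v in g.vertices
    }
    closed_key = {
        v: (g.out_set(v) | {v}, g.in_set(v) | {v}) for v in g.vertices
    }
    assigned: set[str] = set()
    classes: list[ParityClass] = []
    for v in g.vertices:
        if v in assigned:
            continue
        false_twins = [
            u
            for u in g.vertices
            if u not in assigned and open_key[u] == open_key[v]
        ]
        if len(false_twins) >= 2:
            members, kind = false_twins, TwinKind.FALSE_TWIN
        else:
            true_twins = [
                u
                for u in g.vertices
                if u not in assigned and closed_key[u] == closed_key[v]
            ]
            if len(true_twins) >= 2:
                members, kind = true_twins, TwinKind.TRUE_TWIN
            else:
                members, kind = [v], TwinKind.FALSE_TWIN
        assigned.update(members)
        classes.append(
            ParityClass(
                members=tuple(members),
                representative=members[0],
                degree=g.degree_pair(v),
                twin_kind=kind,
            )
        )
    return classes


def _degree_classes(g: DirectedGraph) -> list[ParityClass]:
    groups: dict[DegreePair, list[str]] = {}
    for v in g.vertices:
        groups.setdefault(g.degree_pair(v), []).append(v)
    classes = []
    for v in g.vertices:  # emit in order of each group's first member
        dp = g.degree_pair(v)
        if dp in groups and groups[dp][0] == v:
            members = groups.pop(dp)
            classes.append(
                ParityClass(
                    members=tuple(members),
                    representative=members[0],
                    degree=dp,
                    twin_kind=TwinKind.FALSE_TWIN,
                )
            )
    return classes


def find_parity_classes(
    g: DirectedGraph, mode: str = "structural"
) -> list[ParityClass]:
    """Partition the vertices into interchangeability classes.

    ``mode='structural'`` (default) returns twin classes safe for
    census-preserving compression; ``mode='degree'`` returns the coarse
    frequency partition by exact ``(d_in, d_out)``.  Singletons are
    included in both modes.
    """
    if mode == "structural":
        return _structural_classes(g)
    if mode == "degree":
        return _degree_classes(g)
    raise ValueError(f"unknown mode {mode!r}; expected 'structural' or 'degree'")


def _check_classes(g: DirectedGraph, classes: Sequence[ParityClass]) -> None:
    seen: set[str] = set()
    for c in classes:
        if not c.members or c.members[0] != c.representative:
            raise ValueError(f"class {c.members} must lead with its representative")
        for v in c.members:
            g.index(v)
            if v in seen:
                raise ValueError(f"vertex {v!r} appears in two classes")
            seen.add(v)
    if seen != set(g.vertices):
        raise ValueError("classes do not cover the vertex set")


def compress(g: DirectedGraph, classes: Sequence[ParityClass]) -> CompressedGraph:
    """Remove all non-representative class members; keep the bookkeeping.

    The retained graph is the induced subgraph on the representatives
    (including all singleton classes); removed vertices and their incident
    edges are preserved verbatim in ``g_p`` / ``g_cv``.
    """
    _check_classes(g, classes)
    removed = {v for c in classes if c.size >= 2 for v in c.members[1:]}
    kept = [v for v in g.vertices if v not in removed]
    g_r = induced_subgraph(g, kept)
    g_cv = tuple(
        (u, v) for u, v in g.edges if u in removed or v in removed
    )
    multiplicity = {c.representative: c.size for c in classes}
    return CompressedGraph(
        g_r=g_r,
        g_p=tuple(v for v in g.vertices if v in removed),
        g_cv=g_cv,
        classes=tuple(classes),
        multiplicity=multiplicity,
        original=g,
    )


@dataclass(frozen=True)
class MultiplicityCensus:
    """Census of the compressed graph, keyed by (Code, class usage).

    A *usage* records how many copies of each parity class an embedding
    consumes, as a sorted tuple of ``(representative, r)`` with r >= 1.
    ``entries[code][usage]`` counts distinct compressed embeddings.
    """

    k: int
    entries: Mapping["Code", Mapping[tuple[tuple[str, int], ...], int]]
    class_sizes: Mapping[str, int]


def expand_census(mc: MultiplicityCensus) -> "SubgraphCensus":
    """Recover the uncompressed census by binomial reweighting.

    An embedding using ``r_c`` copies of class ``c`` stands for
    ``prod_c C(size_c, r_c)`` embeddings of the original graph, all with
    the same canonical Code (twin swaps are automorphisms).
    """
    from .enumeration import SubgraphCensus

    counts: dict["Code", int] = {}
    for code, usages in mc.entries.items():
        total = 0
        for usage, n in usages.items():
            w = 1
            for rep, r in usage:
                w *= comb(mc.class_sizes[rep], r)
            total += n * w
        counts[code] = counts.get(code, 0) + total
    return SubgraphCensus(k=mc.k, counts=counts)
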