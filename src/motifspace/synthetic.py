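"""Seeded generators with known ground truth for exercising the pipeline.

Everything here is a pure function of its arguments: the same seed gives
a bitwise-identical graph, so test fixtures need no stored files.
"""

from __future__ import annotations

import random
from typing import Sequence

from .compression import ParityClass, TwinKind
from .graph_core import DegreePair, DirectedGraph, induced_subgraph

__all__ = ["plant_motif", "plant_twins", "random_digraph", "feed_forward_loop"]


def random_digraph(n: int, m: int, seed: int) -> DirectedGraph:
    """Uniform simple digraph on ``v0..v{n-1}`` with exactly *m* edges."""
    if n < 0 or m < 0 or m > n * (n - 1):
        raise ValueError(f"infeasible ({n} vertices, {m} edges)")
    rng = random.Random(seed)
    labels = [f"v{i}" for i in range(n)]
    pairs = [(u, v) for u in labels for v in labels if u != v]
    return DirectedGraph(vertices=labels, edges=sorted(rng.sample(pairs, m)))


def _fresh_labels(g: DirectedGraph, prefix: str, count: int) -> list[str]:
    labels, i = [], 0
    while len(labels) < count:
        cand = f"{prefix}{i}"
        if cand not in g:
            labels.append(cand)
        i += 1
    return labels


def plant_twins(
    g: DirectedGraph,
    class_spec: Sequence[tuple[int, TwinKind | str]],
    seed: int,
) -> tuple[DirectedGraph, list[ParityClass]]:
    """Add vertex classes with shared random external neighborhoods.

    For each ``(size, kind)`` the new vertices get one randomly drawn
    out-set and in-set among the *pre-existing* vertices, plus uniform
    intra-class adjacency (none for false twins, all mutual pairs for
    true twins).  Returns the grown graph and the planted ground-truth
    classes; structural twin detection must recover each as a subset of
    one reported class.
    """
    rng = random.Random(seed)
    base = list(g.vertices)
    if not base:
        raise ValueError("need a non-empty background graph")
    out = DirectedGraph(vertices=g.vertices, edges=g.edges)
    truth: list[ParityClass] = []
    for ci, (size, kind) in enumerate(class_spec):
        kind = TwinKind(kind)
        members = _fresh_labels(out, f"tw{ci}_", size)
        n_out = rng.randint(1, min(3, len(base)))
        n_in = rng.randint(0, min(3, len(base)))
        out_nbrs = sorted(rng.sample(base, n_out))
        in_nbrs = sorted(rng.sample(base, n_in))
        for v in members:
            out.add_vertex(v)
        for v in members:
            for t in out_nbrs:
                out.add_edge(v, t)
            for s in in_nbrs:
                out.add_edge(s, v)
        if kind is TwinKind.TRUE_TWIN:
            for u in members:
                for v in members:
                    if u != v:
                        out.add_edge(u, v)
        intra = size - 1 if kind is TwinKind.TRUE_TWIN else 0
        truth.append(
            ParityClass(
                members=tuple(members),
                representative=members[0],
                degree=DegreePair(d_in=len(in_nbrs) + intra, d_out=len(out_nbrs) + intra),
                twin_kind=kind,
            )
        )
    return out, truth


def feed_forward_loop() -> DirectedGraph:
    """The 3-vertex pattern a->b, a->c, b->c."""
    return DirectedGraph(edges=[("a", "b"), ("a", "c"), ("b", "c")])


def plant_motif(
    g: DirectedGraph, pattern: DirectedGraph, n_copies: int, seed: int
) -> DirectedGraph:
    """Insert vertex-disjoint copies of *pattern* on fresh vertices.

    Copies attach no edges to the rest of the graph, so the census count
    of the pattern's code at k = |pattern| is at least *n_copies* by
    construction (the background is *g* itself, left untouched).
    """
    if pattern.n_vertices > 5:
        raise ValueError("pattern limited to 5 vertices")
    from .graph_core import is_weakly_connected

    if not is_weakly_connected(pattern):
        raise ValueError("pattern must be weakly connected")
    out = DirectedGraph(vertices=g.vertices, edges=g.edges)
    pidx = {v: i for i, v in enumerate(pattern.vertices)}
    for c in range(n_copies):
        labels = _fresh_labels(out, f"m{c}_", pattern.n_vertices)
        for v in labels:
            out.add_vertex(v)
        for u, v in pattern.edges:
            out.add_edge(labels[pidx[u]], labels[pidx[v]])
    return out
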