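"""Degree-preserving randomization by Markov-chain two-edge swaps.

Each trial draws two distinct edges (a->b, c->d) uniformly and rewires
them to (a->d, c->b) when that creates neither a self-loop nor an existing
edge; rejected proposals still consume a trial (pure Markov-chain
semantics, deterministic run length).  Every vertex keeps its exact
(d_in, d_out) pair, so the ensemble realizes the standard null model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterator

from .graph_core import DirectedGraph

__all__ = ["EnsembleSpec", "generate_ensemble", "swap_randomize"]

DEFAULT_ATTEMPTS_PER_EDGE = 10


@dataclass(frozen=True)
class EnsembleSpec:
    """Size, mixing length, and seed of a randomized ensemble."""

    n_networks: int = 1000
    attempts_per_edge: int = DEFAULT_ATTEMPTS_PER_EDGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")
        if self.attempts_per_edge < 1:
            raise ValueError("attempts_per_edge must be >= 1")


def swap_randomize(g: DirectedGraph, attempts: int, seed: int | None) -> DirectedGraph:
    """Return a degree-preserving randomization of *g*.

    Performs exactly *attempts* proposal trials; graphs admitting no valid
    swap come back unchanged.  Deterministic given *seed*.
    """
    rng = random.Random(seed)
    edges = list(g.edges)
    edge_set = set(edges)
    m = len(edges)
    if m < 2:
        return DirectedGraph(vertices=g.vertices, edges=edges)
    for _ in range(attempts):
        i = rng.randrange(m)
        j = rng.randrange(m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue
        e1, e2 = (a, d), (c, b)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.remove((a, b))
        edge_set.remove((c, d))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
    return DirectedGraph(vertices=g.vertices, edges=edges)


def generate_ensemble(g: DirectedGraph, spec: EnsembleSpec) -> Iterator[DirectedGraph]:
    """Yield ``spec.n_networks`` independent randomizations of *g*.

    Member i is seeded with ``spec.seed + i`` and mixed for
    ``spec.attempts_per_edge * |E|`` trials; fully reproducible.
    """
    attempts = spec.attempts_per_edge * g.n_edges
    for i in range(spec.n_networks):
        yield swap_randomize(g, attempts, spec.seed + i)
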