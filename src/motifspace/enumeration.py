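"""Enumeration of connected induced k-subgraphs and canonical-code censuses.

The enumerator is ESU-style: grow each subgraph from its minimum-order
anchor vertex, extending only through exclusive neighbors with order
greater than the anchor, so that every weakly-connected induced vertex set
of size k is produced exactly once, in a deterministic order.  The sampled
variant flips a seeded coin at each extension depth and attaches the
inverse-probability weight, giving unbiased weighted counts.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .codec import MAX_CANONICAL_VERTICES, Code, _canonical_code_indexed
from .compression import CompressedGraph, MultiplicityCensus, expand_census
from .graph_core import DirectedGraph, induced_subgraph

__all__ = [
    "SubgraphCensus",
    "census_compressed",
    "enumerate_connected_subsets",
    "subgraph_census",
]


@dataclass(frozen=True)
class SubgraphCensus:
    """Counts of connected induced k-subgraphs keyed by canonical Code.

    Counts are integers in exact modes and floats (inverse-probability
    weights) in sampled mode.
    """

    k: int
    counts: Mapping[Code, float]

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def count(self, code: Code) -> float:
        return self.counts.get(code, 0)


def _validate_k(g: DirectedGraph, k: int) -> None:
    hi = min(g.n_vertices, MAX_CANONICAL_VERTICES)
    if not 2 <= k <= hi:
        raise ValueError(f"k must satisfy 2 <= k <= {hi}, got {k}")


def enumerate_connected_subsets(
    g: DirectedGraph,
    k: int,
    sample_probs: Sequence[float] | None = None,
    seed: int | None = None,
) -> Iterator[tuple[tuple[str, ...], float]]:
    """Yield each weakly-connected induced k-subset exactly once.

    Yields ``(vertices, weight)`` pairs; vertices sorted by input order.
    In exact mode (no *sample_probs*) the weight is 1 and every qualifying
    set appears.  With *sample_probs* (one probability per depth, each in
    (0, 1]) the extension at depth d is taken with probability
    ``sample_probs[d]`` using a generator seeded with *seed*, and each
    yielded set carries weight ``1 / prod(sample_probs)`` so that expected
    weighted counts equal exact counts.
    """
    _validate_k(g, k)
    probs: list[float] | None = None
    if sample_probs is not None:
        probs = [float(p) for p in sample_probs]
        if len(probs) != k:
            raise ValueError(f"sample_probs must have length k={k}")
        if any(not 0 < p <= 1 for p in probs):
            raise ValueError("sample_probs entries must lie in (0, 1]")
    rng = random.Random(seed)
    weight = 1.0 / math.prod(probs) if probs else 1.0

    order = g.vertices
    idx = {v: i for i, v in enumerate(order)}
    nbrs: list[tuple[int, ...]] = []
    for v in order:
        und = {idx[u] for u in g.out_neighbors(v)} | {
            idx[u] for u in g.in_neighbors(v)
        }
        nbrs.append(tuple(sorted(und)))

    def take(depth: int) -> bool:
        if probs is None:
            return True
        p = probs[depth]
        return p >= 1.0 or rng.random() < p

    def extend(
        sub: list[int], ext: list[int], closed: set[int], anchor: int
    ) -> Iterator[tuple[tuple[str, ...], float]]:
        if len(sub) == k:
            yield tuple(order[i] for i in sorted(sub)), weight
            return
        while ext:
            w = ext.pop(0)
            if not take(len(sub)):
                continue
            new_closed = closed | set(nbrs[w])
            excl = [
                u
                for u in nbrs[w]
                if u > anchor and u not in closed
            ]
            yield from extend(sub + [w], sorted(ext + excl), new_closed, anchor)

    n = len(order)
    for v in range(n):
        if not take(0):
            continue
        ext0 = [u for u in nbrs[v] if u > v]
        closed0 = {v} | {u for u in nbrs[v]}
        yield from extend([v], ext0, closed0, v)


def _census_from_sets(
    g: DirectedGraph,
    k: int,
    sets: Iterator[tuple[tuple[str, ...], float]],
    cache: dict | None = None,
) -> dict[Code, float]:
    """Aggregate canonical codes over enumerated vertex sets.

    Codes are memoized by the labeled adjacency pattern of the subset
    (index pairs relative to the subset's own order), which collapses the
    permutation search to one run per labeled pattern.
    """
    idx = {v: i for i, v in enumerate(g.vertices)}
    code_cache: dict[tuple, Code] = cache if cache is not None else {}
    counts: dict[Code, float] = {}
    for vs, w in sets:
        pos = {v: i for i, v in enumerate(vs)}
        sig = tuple(
            sorted(
                (pos[u], pos[v])
                for u in vs
                for v in vs
                if u != v and g.has_edge(u, v)
            )
        )
        code = code_cache.get(sig)
        if code is None:
            code = _canonical_code_indexed(k, list(sig))
            code_cache[sig] = code
        counts[code] = counts.get(code, 0) + w
    return counts


def subgraph_census(
    g: DirectedGraph,
    k: int,
    sample_probs: Sequence[float] | None = None,
    seed: int | None = None,
) -> SubgraphCensus:
    """Census of all weakly-connected induced k-subgraphs of *g*.

    Deterministic given *seed*; exact integer counts when *sample_probs*
    is omitted.
    """
    sets = enumerate_connected_subsets(g, k, sample_probs=sample_probs, seed=seed)
    counts = _census_from_sets(g, k, sets)
    if sample_probs is None:
        counts = {c: int(round(w)) for c, w in counts.items()}
    return SubgraphCensus(k=k, counts=counts)


def _multiplicity_census(cg: CompressedGraph, k: int) -> MultiplicityCensus:
    """Enumerate compressed embeddings with class multiplicities.

    Works on a *capped* graph holding, for each parity class, its first
    ``min(size, k)`` members (twin uniformity makes any members
    interchangeable).  An embedding choosing r copies of a class is
    enumerated once, in its canonical form using the first r members;
    subsets using a non-prefix selection are discarded as duplicates.
    """
    g = cg.original
    rank: dict[str, tuple[str, int]] = {}  # vertex -> (representative, rank)
    keep: set[str] = set()
    for c in cg.classes:
        used = c.members[: min(c.size, k)]
        keep.update(used)
        for r, v in enumerate(c.members):
            rank[v] = (c.representative, r)
    capped = induced_subgraph(g, keep)

    entries: dict[Code, dict[tuple[tuple[str, int], ...], int]] = {}
    cache: dict = {}
    for vs, _w in enumerate_connected_subsets(capped, k):
        usage_count: dict[str, int] = {}
        max_rank: dict[str, int] = {}
        for v in vs:
            rep, r = rank[v]
            usage_count[rep] = usage_count.get(rep, 0) + 1
            max_rank[rep] = max(max_rank.get(rep, -1), r)
        # prefix rule: copies of a class must be its lowest-rank members
        if any(max_rank[rep] != usage_count[rep] - 1 for rep in usage_count):
            continue
        counts = _census_from_sets(
            capped, k, iter([(vs, 1.0)]), cache=cache
        )
        (code,) = counts
        usage = tuple(sorted(usage_count.items()))
        entries.setdefault(code, {})
        entries[code][usage] = entries[code].get(usage, 0) + 1
    return MultiplicityCensus(
        k=k,
        entries=entries,
        class_sizes=dict(cg.multiplicity),
    )


def census_compressed(
    cg: CompressedGraph, k: int, expand: bool = True
) -> SubgraphCensus:
    """Census over a compressed graph.

    ``expand=False`` is the fast workflow: a plain census of the retained
    graph ``g_r`` (real and random networks must then be compressed the
    same way to stay comparable).  ``expand=True`` enumerates with class
    multiplicities and reweights, reproducing the census of the original
    graph exactly.
    """
    if not expand:
        return subgraph_census(cg.g_r, k)
    return expand_census(_multiplicity_census(cg, k))
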