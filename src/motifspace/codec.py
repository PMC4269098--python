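"""Balanced-ternary encoding of incidence matrices and canonical class codes.

An incidence matrix is flattened row-major into digits in {-1, 0, +1} and
read as a balanced-ternary integer (the *Code*).  The canonical code of a
small connected digraph is the maximum code over all vertex orderings, with
edge columns sorted by (source index, target index) under each ordering —
a well-defined, isomorphism-invariant mark.  A plain permutation-search
isomorphism oracle is provided for independent verification.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np

from .graph_core import DirectedGraph, IncidenceMatrix, is_weakly_connected

__all__ = [
    "MAX_CANONICAL_VERTICES",
    "Code",
    "are_isomorphic_bruteforce",
    "canonical_code",
    "code_to_edges",
    "code_to_graph",
    "decode_symmetric_ternary",
    "encode_symmetric_ternary",
]

#: canonical_code searches k! orderings; beyond this the search is refused.
MAX_CANONICAL_VERTICES = 8


@dataclass(frozen=True, order=True)
class Code:
    """Balanced-ternary integer plus the matrix shape it encodes.

    The shape is part of identity: the same integer read at different
    shapes denotes different matrices.
    """

    value: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        bound = (3 ** (self.n_rows * self.n_cols) - 1) // 2
        if abs(self.value) > bound:
            raise ValueError(
                f"|value| {abs(self.value)} exceeds balanced-ternary bound "
                f"{bound} for a {self.n_rows}x{self.n_cols} matrix"
            )

    def __str__(self) -> str:
        return str(self.value)


def _digits_to_value(digits: Iterable[int]) -> int:
    value = 0
    for d in digits:
        if d not in (-1, 0, 1):
            raise ValueError(f"digit {d!r} outside {{-1, 0, +1}}")
        value = value * 3 + d
    return value


def encode_symmetric_ternary(m: IncidenceMatrix | Sequence[Sequence[int]]) -> Code:
    """Read a {-1,0,+1} matrix row-major as a balanced-ternary integer.

    The first (row 0, column 0) entry is the most significant digit.
    Exact arbitrary-precision arithmetic throughout.
    """
    grid = m.entries if isinstance(m, IncidenceMatrix) else np.asarray(m)
    if grid.ndim != 2:
        raise ValueError("expected a 2-dimensional grid")
    n_rows, n_cols = grid.shape
    value = _digits_to_value(int(d) for d in grid.reshape(-1))
    return Code(value=value, n_rows=n_rows, n_cols=n_cols)


def decode_symmetric_ternary(c: Code) -> list[list[int]]:
    """Exact left inverse of :func:`encode_symmetric_ternary`.

    Returns the digit grid as nested lists (it need not satisfy the
    incidence-column invariant; arbitrary ternary grids round-trip).
    """
    n = c.n_rows * c.n_cols
    digits = [0] * n
    r = c.value
    for i in range(n - 1, -1, -1):
        d = (r + 1) % 3 - 1
        digits[i] = d
        r = (r - d) // 3
    if r != 0:
        raise ValueError("value out of range for the stated shape")
    return [digits[i * c.n_cols : (i + 1) * c.n_cols] for i in range(c.n_rows)]


def _canonical_code_indexed(n: int, edges: Sequence[tuple[int, int]]) -> Code:
    """Canonical code of a digraph given as index pairs on ``range(n)``.

    Maximum over all vertex orderings of the row-major balanced-ternary
    value of the incidence matrix whose columns are sorted ascending by
    (source position, target position).
    """
    m = len(edges)
    n_digits = n * m
    pow3 = [3**i for i in range(n_digits)]
    best: int | None = None
    for perm in permutations(range(n)):
        cols = sorted((perm[s], perm[t]) for s, t in edges)
        value = 0
        for j, (ps, pt) in enumerate(cols):
            value += pow3[n_digits - 1 - (ps * m + j)]
            value -= pow3[n_digits - 1 - (pt * m + j)]
        if best is None or value > best:
            best = value
    return Code(value=best if best is not None else 0, n_rows=n, n_cols=m)


def canonical_code(g: DirectedGraph) -> Code:
    """Isomorphism-class mark of a weakly connected digraph on 2..8 vertices.

    Equal for isomorphic graphs, distinct otherwise (verified against the
    brute-force oracle in the test suite).
    """
    n = g.n_vertices
    if n < 2 or n > MAX_CANONICAL_VERTICES:
        raise ValueError(
            f"canonical_code requires 2 <= |V| <= {MAX_CANONICAL_VERTICES}, got {n}"
        )
    if not is_weakly_connected(g):
        raise ValueError("canonical_code requires a weakly connected graph")
    idx = {v: i for i, v in enumerate(g.vertices)}
    edges = [(idx[u], idx[v]) for u, v in g.edges]
    return _canonical_code_indexed(n, edges)


def code_to_edges(c: Code) -> list[tuple[int, int]]:
    """Edge list (source row, target row) of the matrix a Code encodes."""
    grid = np.asarray(decode_symmetric_ternary(c))
    edges = []
    for j in range(c.n_cols):
        col = grid[:, j]
        (src,) = np.flatnonzero(col == 1)
        (tgt,) = np.flatnonzero(col == -1)
        edges.append((int(src), int(tgt)))
    return edges


def code_to_graph(c: Code) -> DirectedGraph:
    """Exemplar digraph of a canonical Code, vertices labeled ``v1..vk``."""
    labels = [f"v{i + 1}" for i in range(c.n_rows)]
    return DirectedGraph(
        vertices=labels,
        edges=[(labels[s], labels[t]) for s, t in code_to_edges(c)],
    )


def are_isomorphic_bruteforce(g1: DirectedGraph, g2: DirectedGraph) -> bool:
    """Plain permutation-search digraph isomorphism test (the oracle).

    Independent of :func:`canonical_code` by design: tries every vertex
    bijection and checks exact directed edge correspondence.
    """
    if g1.n_vertices > 8 or g2.n_vertices > 8:
        raise ValueError("brute-force oracle limited to 8 vertices")
    if g1.n_vertices != g2.n_vertices or g1.n_edges != g2.n_edges:
        return False
    v1 = g1.vertices
    e1 = g1.edges
    target = set(g2.edges)
    for image in permutations(g2.vertices):
        f = dict(zip(v1, image))
        if all((f[u], f[v]) in target for u, v in e1):
            return True
    return False
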