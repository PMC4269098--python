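"""Motif calling: real-network census vs a degree-preserving ensemble.

A subgraph class is a motif when all three criteria hold:

1. empirical right-tail frequency P < 0.01 over the ensemble,
2. the real count is larger than four (strictly), and
3. N_real - N_rand > 0.1 * N_rand, with N_rand the ensemble mean.

P counts ties as exceedances; no pseudo-count correction and no
multiple-testing adjustment across classes (each class is judged on its
own, which is a caveat for wide censuses).  The z-score is reported for
ranking only and plays no part in the decision.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .codec import Code
from .compression import compress, find_parity_classes
from .enumeration import SubgraphCensus, census_compressed, subgraph_census
from .graph_core import DirectedGraph
from .nullmodel import EnsembleSpec, generate_ensemble

__all__ = [
    "MotifReport",
    "MotifVerdict",
    "empirical_p",
    "mine_motifs",
    "motif_decision",
]

COMPRESSION_MODES = ("off", "fast", "exact")


@dataclass(frozen=True)
class MotifVerdict:
    code: Code
    n_real: float
    n_rand_mean: float
    n_rand_sd: float
    p_value: float
    z_score: float  # NaN when the ensemble sd is zero
    is_motif: bool


@dataclass(frozen=True)
class MotifReport:
    k: int
    verdicts: tuple[MotifVerdict, ...]
    metadata: Mapping[str, object] = field(default_factory=dict)

    @property
    def motifs(self) -> tuple[MotifVerdict, ...]:
        return tuple(v for v in self.verdicts if v.is_motif)


def empirical_p(n_real: float, rand_counts: Sequence[float]) -> float:
    """Right-tail frequency: fraction of ensemble counts >= n_real."""
    if not rand_counts:
        raise ValueError("empirical_p requires a non-empty ensemble")
    return sum(1 for c in rand_counts if c >= n_real) / len(rand_counts)


def motif_decision(
    n_real: float, rand_counts: Sequence[float], code: Code | None = None
) -> MotifVerdict:
    """Apply the three motif criteria to one subgraph class."""
    p = empirical_p(n_real, rand_counts)
    mean = statistics.fmean(rand_counts)
    sd = statistics.pstdev(rand_counts)
    z = (n_real - mean) / sd if sd > 0 else math.nan
    is_motif = p < 0.01 and n_real > 4 and (n_real - mean) > 0.1 * mean
    return MotifVerdict(
        code=code,
        n_real=n_real,
        n_rand_mean=mean,
        n_rand_sd=sd,
        p_value=p,
        z_score=z,
        is_motif=is_motif,
    )


def _census_with_mode(g: DirectedGraph, k: int, mode: str) -> SubgraphCensus:
    if mode == "off":
        return subgraph_census(g, k)
    cg = compress(g, find_parity_classes(g, mode="structural"))
    return census_compressed(cg, k, expand=(mode == "exact"))


def _verdict_sort_key(v: MotifVerdict):
    nan = math.isnan(v.z_score)
    return (nan, -(0.0 if nan else v.z_score), -v.n_real, -v.code.value)


def mine_motifs(
    g: DirectedGraph,
    k: int,
    spec: EnsembleSpec,
    compression_mode: str = "off",
) -> MotifReport:
    """Full motif-mining run: census, ensemble, three-criterion verdicts.

    Every ensemble member is processed with the same compression mode as
    the input graph so the censuses stay comparable; codes absent from a
    member count as zero there.  Verdicts are sorted by descending
    z-score (NaN last).  Reproducible end to end from ``spec.seed``.
    """
    if compression_mode not in COMPRESSION_MODES:
        raise ValueError(
            f"compression_mode must be one of {COMPRESSION_MODES}, got "
            f"{compression_mode!r}"
        )
    real = _census_with_mode(g, k, compression_mode)
    codes = sorted(real.counts, key=lambda c: (-real.counts[c], -c.value))
    rand_counts: dict[Code, list[float]] = {c: [] for c in codes}
    for member in generate_ensemble(g, spec):
        census = _census_with_mode(member, k, compression_mode)
        for c in codes:
            rand_counts[c].append(census.count(c))
    verdicts = sorted(
        (motif_decision(real.counts[c], rand_counts[c], code=c) for c in codes),
        key=_verdict_sort_key,
    )
    metadata = {
        "k": k,
        "n_networks": spec.n_networks,
        "attempts_per_edge": spec.attempts_per_edge,
        "seed": spec.seed,
        "compression_mode": compression_mode,
        "n_vertices": g.n_vertices,
        "n_edges": g.n_edges,
    }
    return MotifReport(k=k, verdicts=tuple(verdicts), metadata=metadata)
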