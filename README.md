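# motifspace

Network-motif mining for directed graphs built around three ideas:

1. **Canonical codes** — every connected k-subgraph (k ≤ 8) is marked by a
   single integer: its incidence matrix (+1 source row, −1 target row) is
   flattened row-major and read as a balanced-ternary number; the canonical
   code is the maximum over vertex orderings with columns sorted by
   (source, target). Isomorphic subgraphs — and only those — share a code
   (verified against an independent brute-force permutation oracle).
2. **Search-space compression** — *parity* (twin) vertices with identical
   external neighborhoods are interchangeable; all but the first-appearing
   member of each class are removed before enumeration. Censuses of the
   compressed graph can be expanded back to exact uncompressed counts by
   binomial reweighting, or compared compressed-vs-compressed (the fast
   workflow, applying the same compression to every randomized network).
3. **Three-criterion motif calls** — a class is a motif when its empirical
   right-tail frequency over a degree-preserving edge-swap ensemble is
   P < 0.01, its real count exceeds four, and it is enriched by more than
   10% over the ensemble mean.

Inputs are plain-text edge lists (`source target` per line, `#` comments,
extra columns ignored), the dialect of the public transcription-network
collections. A seeded synthetic module generates graphs with planted twin
classes and planted motif copies, so nothing needs downloading to test.

## CLI

```sh
# count connected induced 3-subgraphs per isomorphism class
motifspace census -k 3 graph.txt

# remove parity nodes (structural twins), keep one representative each
motifspace compress graph.txt --out-graph retained.txt --out-classes classes.tsv

# degree-preserving randomized copies
motifspace randomize graph.txt --count 1000 --seed 1 --out-dir ensemble/

# full motif mine: census vs 1000-network ensemble, three criteria
motifspace mine -k 3 --random 1000 --seed 1 --out report.tsv graph.txt

# seeded synthetic graph with planted twin classes / motif copies
motifspace synth --nodes 30 --edges 45 --seed 7 --twin 3:false_twin --out g.txt
```

All tabular output is TSV with decimal-string codes; stochastic runs write a
`.meta.json` sidecar recording seed and flags. `--config file` supplies
flat `key=value` defaults; logs go to stderr.

## Library

```python
from motifspace import (
    read_edge_list, subgraph_census, find_parity_classes, compress,
    census_compressed, mine_motifs, EnsembleSpec,
)

g = read_edge_list("graph.txt")
census = subgraph_census(g, k=3)                       # Code -> count
cg = compress(g, find_parity_classes(g))               # twin compression
assert census_compressed(cg, 3, expand=True).counts == census.counts
report = mine_motifs(g, 3, EnsembleSpec(n_networks=1000, seed=1))
```

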