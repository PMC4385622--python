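# Methods

## Model

`seedpath` operates on a heterogeneous undirected graph *G* = (*V*, *E*)
whose nodes are proteins and chemicals and whose edges come from three
interaction classes (protein-protein, chemical-chemical, chemical-protein),
each scored with an integer combined confidence *S* ∈ [1, 999] on the
STRING/STITCH scale. Edge weights are *w* = 1000 − *S*, kept as exact
integers: path lengths are then exact sums and equal-weight ties can be
detected unambiguously, which matters for deterministic tie-breaking. A
score of 0 encodes the absence of an interaction in the source databases;
it is rejected both at parse time and by the weight transform, so "no
interaction" is always the absence of an edge, never a weight-1000 edge.

The statistic is a *seed-restricted* betweenness. Given seed nodes (known
disease genes and chemicals, pooled into one set), every unordered pair of
distinct seeds contributes one minimum-weight path (default) or all of its
minimum-weight paths; every node strictly inside such a path gains one
count. Endpoints never count toward their own pair. This differs from
standard betweenness centrality in two ways: only seed pairs contribute,
and whole paths are counted rather than fractional pair-dependencies.
Nodes with positive count are candidates; by default seed nodes themselves
are excluded from the candidate output (they are already known) and are
reported separately.

Significance is assessed by permutation: random seed sets of matched
composition — exactly as many protein nodes and chemical nodes as the
*mapped* true seed set — are drawn uniformly without replacement from all
graph nodes of each class (true seeds are not excluded: no exclusion is
part of the procedure's definition). For each candidate, the reported
"fdr" is the fraction of null sets on which its betweenness strictly
exceeds the observed value. Operationally this is a per-node permutation
p-value; the historical column name is kept in outputs. The significance
filter is strict (`fdr < threshold`), so at the default 0.05 with 1000
permutations a candidate may be beaten in at most 49 null sets.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `path_mode` | `single_path` | one deterministic shortest path per seed pair; `all_paths` counts every minimum-weight path |
| `duplicate_policy` | `max` | repeated unordered interaction pairs keep the maximum score (minimum weight); source dumps list both orientations of each pair, so a merge rule is mandatory |
| `n_permutations` | 1000 | null-set count; FDR granularity is 1/N |
| `comparator` | `strictly_greater` | null-beats-observed rule; `greater_or_equal` is the conventional permutation-p alternative, differing only on ties |
| `threshold` | 0.05 | strict significance cut on the permutation FDR |
| `include_seeds` | `False` | whether seed nodes with positive betweenness appear among candidates |
| `rng_seed` | — | single seed from which all null draws flow |

Composition matching uses the number of seeds actually *mapped* into the
graph, not the nominal list lengths: unmapped seeds contribute no paths, so
matching nominal counts would bias the null upward.

## Numerical and design choices

**Tie-breaking.** Dijkstra distances are computed with networkx; the single
path per pair is then reconstructed greedily on the shortest-path DAG: at
each node, the next hop is the smallest-id neighbor that still lies on a
minimum-weight continuation. Greedy selection at each position yields the
lexicographically smallest node-id sequence among all minimum-weight paths,
a rule that is independent of adjacency iteration order and reproducible
across runs and implementations. `all_paths` mode enumerates the full set
of minimum-weight paths instead; it is exact but can be exponential in
pathological tie-rich graphs, which is why `single_path` is the default.

**Degenerate inputs.** Disconnected seed pairs are skipped and tallied,
never fatal (real interactome subgraphs are not guaranteed connected).
Seed identifiers are matched to nodes by exact string equality; identifier
namespace mapping (gene symbol vs Ensembl protein id vs PubChem CID) is
deliberately left to the caller. A seed identifier supplied in the wrong
list is classified by its graph kind, with a warning. An identifier
appearing as both protein and chemical is a construction error. Fewer than
two mapped seeds is an error (no pairs exist).

**Null-set protocol.** One `numpy.random.Generator` is seeded from
`rng_seed`; per permutation, one `choice` call draws the protein ids from
the ascending-sorted protein list, then one draws the chemical ids. The
protocol is documented precisely so that independent implementations can
replay the identical stream; the test suite contains such a from-scratch
replay. Null betweenness is tracked only for candidate nodes, which bounds
memory on large graphs.

## The synthetic generator

The generator emulates the *structure* of the real inputs, not their
statistics: two node classes, three dialect tables, integer scores in
[1, 999]. Background edges are Erdős–Rényi within and between classes with
uniform scores on a configurable range; the planted signal is a set of
"linker" nodes, each wired to `min(3, n_seeds)` randomly chosen seeds with
scores from a range strictly above the background (so linker edges have
strictly smaller weights and a two-hop seed–linker–seed route undercuts any
background route). Three edges per linker is the smallest wiring that gives
each linker several guaranteed seed-pair paths while leaving the detection
problem nontrivial. The reference conditions are 60 proteins, 20
chemicals, density 0.05, background scores 150–400, 8 + 3 seeds, 5 linkers
at scores 900–990, and 200 permutations.

The generator does **not** reproduce the degree distribution, score
distribution, or scale of real STRING/STITCH dumps (millions of edges, many
high scores). Passing the planted-linker benchmark therefore shows that the
pipeline's plumbing, statistic and null are correct and reproducible — not
that the method has any particular sensitivity on a real interactome.

## Known limitations

- **The permutation null is conservative for planted hub-like structure.**
  Because the null conditions on the graph, any node made central by
  strong edges is central for *random* seed sets too: in the synthetic
  benchmark, the linker–seed corridor is the only low-weight structure, so
  null seed pairs also route through the linkers, and a linker's null
  betweenness distribution (95th percentile ≈ 16–26 of 55 pairs on the
  reference instance) overlaps its observed value (13–33). Typically only
  the strongest one or two linkers per instance clear fdr < 0.05, although
  linkers separate cleanly from decoys by FDR rank (median decoy FDR 1.0 vs
  median linker FDR ≈ 0.1). On a real interactome, where high scores are
  ubiquitous rather than concentrated on the planted signal, this
  self-conditioning is exactly the property that suppresses generic hubs.
- The per-node permutation fraction is not a false-discovery-rate estimate
  across candidates; no multiplicity correction is applied, by design.
- In `single_path` mode the chosen path among ties is a convention;
  betweenness of nodes that appear only on some tied paths depends on it.
  `all_paths` mode removes the convention at the cost of counting each
  pair with multiplicity.
- Problem sizes in the test suite and the acceptance script (≤ 8-node
  graphs for brute-force oracles, the 80-node reference benchmark with 200
  permutations and 20 replicates) were chosen so exhaustive enumeration
  stays exact and benchmark estimates are stable at a few percent.
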