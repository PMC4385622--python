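"""Seed-restricted shortest-path betweenness.

For a set of seed nodes (known disease genes and chemicals, pooled), every
unordered pair of distinct seeds is connected by a minimum-weight path
(Dijkstra on the 1000-score weights), and each graph node is scored by the
number of such paths on which it appears as an *inner* node -- strictly
between the endpoints.  This differs from ordinary betweenness centrality:
only seed pairs contribute, and counts are whole paths, not fractions.

Two path-multiplicity modes are supported:

``single_path``
    One deterministic shortest path per seed pair -- among equal-weight
    alternatives, the path that is lexicographically smallest as a
    sequence of node ids.  This is the default: a plain Dijkstra run
    yields one path per pair, and the lexicographic rule makes that path
    independent of adjacency iteration order.
``all_paths``
    Every minimum-weight path contributes: a node gains +1 for each
    shortest path (not each pair) containing it as an inner node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import networkx as nx

from .errors import DomainError
from .graph import CHEMICAL, PROTEIN, HybridGraph, NodeRef

logger = logging.getLogger(__name__)

MODES = ("single_path", "all_paths")


@dataclass(frozen=True)
class SeedSet:
    """Seed nodes mapped onto a graph, partitioned by node class."""

    genes: tuple[NodeRef, ...]
    chemicals: tuple[NodeRef, ...]
    unmapped: tuple[str, ...] = ()

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_chems(self) -> int:
        return len(self.chemicals)

    @property
    def members(self) -> tuple[NodeRef, ...]:
        """Genes and chemicals pooled (seed pairs draw from both classes)."""
        return self.genes + self.chemicals

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(r.id for r in self.members)


@dataclass(frozen=True)
class PathResult:
    """One minimum-weight path between two nodes."""

    source: NodeRef
    target: NodeRef
    total_weight: int
    node_sequence: tuple[NodeRef, ...]

    @property
    def inner_nodes(self) -> tuple[NodeRef, ...]:
        return self.node_sequence[1:-1]


@dataclass
class BetweennessTable:
    """Per-node inner-path counts for one seed set.

    ``counts`` stores only the nodes with a positive count; ``count()``
    returns 0 for everything else.  ``mode`` records the path-multiplicity
    mode the table was computed under, so a permutation run can refuse to
    compare tables computed under different statistics.
    """

    counts: dict[NodeRef, int]
    pairs_evaluated: int
    pairs_disconnected: int
    mode: str = "single_path"

    def count(self, node: NodeRef) -> int:
        return self.counts.get(node, 0)

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CandidateRecord:
    """A candidate node: observed betweenness, later a permutation FDR."""

    node: NodeRef
    betweenness: int
    fdr: Optional[float] = None
    exceed_count: Optional[int] = None


class CandidateList(list):
    """Candidate records, with the seed nodes that also had positive
    betweenness reported separately on ``seed_hits``."""

    def __init__(self, records: Iterable[CandidateRecord] = (), seed_hits: Sequence[CandidateRecord] = ()):
        super().__init__(records)
        self.seed_hits: list[CandidateRecord] = list(seed_hits)


def map_seeds(
    graph: HybridGraph,
    gene_ids: Iterable[str],
    chemical_ids: Iterable[str],
) -> SeedSet:
    """Match seed identifiers against the graph by exact string equality.

    Seeds present in the graph are partitioned by their *graph* kind
    (an identifier supplied in the gene list but known to the graph as a
    chemical is classified as a chemical, with a warning).  Absent
    identifiers are collected in ``unmapped``.  Raises
    :class:`DomainError` when no seed maps at all.
    """
    gene_ids = [r.id if isinstance(r, NodeRef) else r for r in gene_ids]
    chemical_ids = [r.id if isinstance(r, NodeRef) else r for r in chemical_ids]

    genes: list[NodeRef] = []
    chems: list[NodeRef] = []
    unmapped: list[str] = []
    seen: set[str] = set()
    for supplied_kind, ids in ((PROTEIN, gene_ids), (CHEMICAL, chemical_ids)):
        for node_id in ids:
            if node_id in seen:
                continue
            seen.add(node_id)
            if node_id not in graph:
                unmapped.append(node_id)
                continue
            actual = graph.kind(node_id)
            if actual != supplied_kind:
                logger.warning(
                    "seed %r supplied as %s but is a %s in the graph; using graph kind",
                    node_id, supplied_kind, actual,
                )
            (genes if actual == PROTEIN else chems).append(NodeRef(node_id, actual))
    if not genes and not chems:
        raise DomainError("no seed identifier maps to a graph node")
    if unmapped:
        logger.info("map_seeds: %d seed identifiers not found in the graph", len(unmapped))
    return SeedSet(tuple(genes), tuple(chems), tuple(unmapped))


# -- path search -------------------------------------------------------


def _check_endpoints(graph: HybridGraph, source: str, target: str) -> None:
    if source == target:
        raise DomainError("source and target must differ")
    for node in (source, target):
        if node not in graph:
            raise DomainError(f"node {node!r} is not in the graph")


def _lex_min_path(g: nx.Graph, source: str, target: str, dist_to_target: dict) -> list[str]:
    """Greedy reconstruction of the lexicographically smallest shortest path.

    ``dist_to_target`` holds Dijkstra distances from ``target`` (the graph
    is undirected, so these are distances *to* the target).  At each node u
    the next hop is the smallest-id neighbor v with
    ``w(u, v) + dist(v) == dist(u)``; choosing greedily at each position
    yields the lexicographic minimum over all minimum-weight paths.
    Weights are >= 1, so the remaining distance strictly decreases and the
    walk terminates.
    """
    path = [source]
    cur = source
    while cur != target:
        remaining = dist_to_target[cur]
        nxt = None
        for v in g.neighbors(cur):
            dv = dist_to_target.get(v)
            if dv is None:
                continue
            if g[cur][v]["weight"] + dv == remaining and (nxt is None or v < nxt):
                nxt = v
        assert nxt is not None, "shortest-path DAG invariant violated"
        path.append(nxt)
        cur = nxt
    return path


def _as_result(graph: HybridGraph, ids: Sequence[str], total_weight: int) -> PathResult:
    seq = tuple(graph.node_ref(n) for n in ids)
    return PathResult(seq[0], seq[-1], total_weight, seq)


def shortest_path(graph: HybridGraph, source: str, target: str) -> Optional[PathResult]:
    """Minimum-weight path from source to target, or None if disconnected.

    Among equal-weight alternatives the returned path is the unique
    lexicographically smallest node-id sequence, so repeated runs (and
    independent implementations following the same rule) agree exactly.
    """
    source = source.id if isinstance(source, NodeRef) else source
    target = target.id if isinstance(target, NodeRef) else target
    _check_endpoints(graph, source, target)
    g = graph.nx
    dist = nx.single_source_dijkstra_path_length(g, target, weight="weight")
    if source not in dist:
        return None
    ids = _lex_min_path(g, source, target, dist)
    return _as_result(graph, ids, dist[source])


def all_shortest_paths(graph: HybridGraph, source: str, target: str) -> list[PathResult]:
    """All minimum-weight paths between two nodes (empty if disconnected).

    Every returned path has the same minimal total weight and the list is
    exhaustive; paths are ordered lexicographically by node-id sequence.
    """
    source = source.id if isinstance(source, NodeRef) else source
    target = target.id if isinstance(target, NodeRef) else target
    _check_endpoints(graph, source, target)
    g = graph.nx
    try:
        total = nx.dijkstra_path_length(g, source, target, weight="weight")
    except nx.NetworkXNoPath:
        return []
    paths = sorted(nx.all_shortest_paths(g, source, target, weight="weight"))
    return [_as_result(graph, p, total) for p in paths]


def seed_betweenness(graph: HybridGraph, seeds: SeedSet, mode: str = "single_path") -> BetweennessTable:
    """Count, for every node, the seed-pair shortest paths it sits inside.

    Iterates over all unordered pairs of distinct seed nodes (genes and
    chemicals pooled).  For each connected pair the count of every strictly
    inner node is incremented: +1 per pair in ``single_path`` mode, +1 per
    minimum-weight path in ``all_paths`` mode.  Path endpoints never
    increment their own pair's counts.  Disconnected pairs are skipped and
    tallied in ``pairs_disconnected``.
    """
    if mode not in MODES:
        raise DomainError(f"mode must be one of {MODES}, got {mode!r}")
    members = sorted(seeds.members, key=lambda r: r.id)
    if len(members) < 2:
        raise DomainError(f"need at least 2 mapped seeds, got {len(members)}")

    g = graph.nx
    counts: dict[NodeRef, int] = {}
    pairs_evaluated = 0
    pairs_disconnected = 0

    if mode == "single_path":
        # one Dijkstra per seed; pair paths are then O(path length) walks
        dist = {s.id: nx.single_source_dijkstra_path_length(g, s.id, weight="weight") for s in members}
        for s, t in combinations(members, 2):
            if t.id not in dist[s.id]:
                pairs_disconnected += 1
                continue
            pairs_evaluated += 1
            ids = _lex_min_path(g, s.id, t.id, dist[t.id])
            for n in ids[1:-1]:
                ref = graph.node_ref(n)
                counts[ref] = counts.get(ref, 0) + 1
    else:
        for s, t in combinations(members, 2):
            paths = all_shortest_paths(graph, s.id, t.id)
            if not paths:
                pairs_disconnected += 1
                continue
            pairs_evaluated += 1
            for p in paths:
                for ref in p.inner_nodes:
                    counts[ref] = counts.get(ref, 0) + 1

    return BetweennessTable(counts, pairs_evaluated, pairs_disconnected, mode)


def select_candidates(
    table: BetweennessTable,
    seeds: SeedSet,
    include_seeds: bool = False,
) -> CandidateList:
    """Nodes with betweenness > 0, the candidate genes and chemicals.

    Seed nodes are excluded from the output by default (candidates are
    *new* genes/chemicals, distinct from the knowns) and reported
    separately on the returned list's ``seed_hits``.  Records are ordered
    by descending betweenness, ties by ascending id, and carry the node
    kind so gene and chemical candidates can be tallied independently.
    """
    seed_ids = seeds.ids
    records: list[CandidateRecord] = []
    seed_hits: list[CandidateRecord] = []
    for node, count in table.counts.items():
        if count <= 0:
            continue
        rec = CandidateRecord(node, count)
        if node.id in seed_ids and not include_seeds:
            seed_hits.append(rec)
        else:
            records.append(rec)
    key = lambda r: (-r.betweenness, r.node.id)
    records.sort(key=key)
    seed_hits.sort(key=key)
    return CandidateList(records, seed_hits)
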