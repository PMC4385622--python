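"""Hybrid weighted graph over protein and chemical nodes.

Nodes come in two classes (proteins and chemicals) and edges in three
interaction classes: protein-protein (PP), chemical-chemical (CC) and
chemical-protein (CP).  Every interaction carries an integer combined
confidence score S in [1, 999]; the graph edge gets weight

    w(e) = 1000 - S

so that strong interactions are short.  A score of 0 encodes "no
interaction" in the source databases and must never appear as an edge.
Shortest paths on these integer weights are exact, so tie detection
between equal-weight paths is unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import networkx as nx

from .errors import DomainError, GraphConstructionError, ValidationError

logger = logging.getLogger(__name__)

PROTEIN = "protein"
CHEMICAL = "chemical"
KINDS = (PROTEIN, CHEMICAL)

SCORE_MIN = 1
SCORE_MAX = 999


@dataclass(frozen=True, order=True)
class NodeRef:
    """A typed node reference: opaque identifier plus node class.

    ``(id, kind)`` is the unique key; the same identifier string may not
    occur with both kinds in one graph.
    """

    id: str
    kind: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("node id must be a non-empty string")
        if self.kind not in KINDS:
            raise ValidationError(f"node kind must be one of {KINDS}, got {self.kind!r}")


@dataclass(frozen=True)
class InteractionRecord:
    """One scored interaction between two typed endpoints.

    The (kind(a), kind(b)) pair determines the interaction class:
    PP, CC, or CP.  ``channel_scores`` optionally keeps the per-channel
    sub-scores (similarity, experiment, database, textmining) from the
    source table; only the combined score is ever used for weighting.
    """

    a: NodeRef
    b: NodeRef
    score: int
    channel_scores: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if self.a.id == self.b.id:
            raise ValidationError(f"self-interaction on {self.a.id!r} is not allowed")
        if not (SCORE_MIN <= self.score <= SCORE_MAX):
            raise ValidationError(
                f"combined score must lie in [{SCORE_MIN}, {SCORE_MAX}], got {self.score}"
            )

    @property
    def interaction_class(self) -> str:
        """'pp', 'cc' or 'cp' from the endpoint kinds."""
        kinds = {self.a.kind, self.b.kind}
        if kinds == {PROTEIN}:
            return "pp"
        if kinds == {CHEMICAL}:
            return "cc"
        return "cp"

    @property
    def key(self) -> frozenset:
        """Unordered endpoint-pair key (edges are undirected)."""
        return frozenset((self.a.id, self.b.id))


def score_to_weight(score: int) -> int:
    """Transform a combined score into an edge weight: ``1000 - score``.

    Strictly decreasing in the score.  Scores outside [1, 999] are a
    domain error -- 0 means the interaction does not exist, hence no
    edge at all rather than a weight-1000 edge.
    """
    if not isinstance(score, (int,)) or isinstance(score, bool):
        raise DomainError(f"score must be an integer, got {score!r}")
    if not (SCORE_MIN <= score <= SCORE_MAX):
        raise DomainError(f"score must lie in [{SCORE_MIN}, {SCORE_MAX}], got {score}")
    return 1000 - score


@dataclass
class BuildReport:
    """Bookkeeping emitted by :func:`build_graph`."""

    n_input: int = 0
    n_dropped_whitelist: int = 0
    n_merged_duplicates: int = 0
    n_edges: int = 0


class HybridGraph:
    """Weighted undirected graph over protein and chemical nodes.

    Thin wrapper around a :class:`networkx.Graph` whose nodes are the
    identifier strings (with a ``kind`` attribute) and whose edges carry
    ``score`` and ``weight`` attributes with ``score + weight == 1000``.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()
        self.build_report = BuildReport()

    # -- construction ---------------------------------------------------

    def _add_node(self, ref: NodeRef) -> None:
        existing = self._g.nodes.get(ref.id)
        if existing is not None and existing["kind"] != ref.kind:
            raise GraphConstructionError(
                f"identifier {ref.id!r} appears as both "
                f"{existing['kind']} and {ref.kind}"
            )
        self._g.add_node(ref.id, kind=ref.kind)

    def _add_edge(self, rec: InteractionRecord) -> None:
        self._add_node(rec.a)
        self._add_node(rec.b)
        self._g.add_edge(rec.a.id, rec.b.id, score=rec.score, weight=score_to_weight(rec.score))

    # -- queries --------------------------------------------------------

    @property
    def nx(self) -> nx.Graph:
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def kind(self, node_id: str) -> str:
        try:
            return self._g.nodes[node_id]["kind"]
        except KeyError:
            raise DomainError(f"node {node_id!r} is not in the graph") from None

    def node_ref(self, node_id: str) -> NodeRef:
        return NodeRef(node_id, self.kind(node_id))

    def nodes(self) -> Iterator[NodeRef]:
        for n, data in self._g.nodes(data=True):
            yield NodeRef(n, data["kind"])

    def ids_of_kind(self, kind: str) -> list[str]:
        """Ascending-sorted identifiers of one node class."""
        if kind not in KINDS:
            raise DomainError(f"unknown node kind {kind!r}")
        return sorted(n for n, d in self._g.nodes(data=True) if d["kind"] == kind)

    def to_records(self) -> list[InteractionRecord]:
        """Edge list as interaction records (sorted, for reproducible dumps)."""
        out = []
        for u, v, data in sorted(self._g.edges(data=True)):
            a, b = sorted((u, v))
            out.append(InteractionRecord(self.node_ref(a), self.node_ref(b), data["score"]))
        out.sort(key=lambda r: (min(r.a.id, r.b.id), max(r.a.id, r.b.id)))
        return out


def build_graph(
    interactions: Iterable[InteractionRecord],
    chemical_whitelist: Optional[set[str]] = None,
    duplicate_policy: str = "max",
) -> HybridGraph:
    """Build the hybrid graph from scored interactions.

    Parameters
    ----------
    interactions
        Valid :class:`InteractionRecord` values of any mix of the three
        interaction classes.
    chemical_whitelist
        If given, every interaction touching a chemical *not* in the set is
        dropped before construction (the source-database restriction that
        chemicals must have records in a curated compound catalogue, e.g.
        KEGG).  Applies to chemical endpoints only.
    duplicate_policy
        ``"max"`` (default): repeated unordered pairs keep the maximum
        score, i.e. the minimum weight -- source dumps list each pair in
        both orientations, so a merge rule is mandatory.  ``"error"``:
        any repeated pair raises :class:`GraphConstructionError`.

    Returns
    -------
    HybridGraph
        Nodes are exactly the endpoints of surviving interactions; dropped
        and merged counts are recorded on ``graph.build_report``.
    """
    if duplicate_policy not in ("max", "error"):
        raise DomainError(f"duplicate_policy must be 'max' or 'error', got {duplicate_policy!r}")

    graph = HybridGraph()
    report = graph.build_report
    best: dict[frozenset, InteractionRecord] = {}
    for rec in interactions:
        report.n_input += 1
        if chemical_whitelist is not None:
            touched = [e for e in (rec.a, rec.b) if e.kind == CHEMICAL]
            if any(e.id not in chemical_whitelist for e in touched):
                report.n_dropped_whitelist += 1
                continue
        key = rec.key
        prev = best.get(key)
        if prev is None:
            best[key] = rec
        else:
            if duplicate_policy == "error":
                raise GraphConstructionError(
                    f"duplicate interaction for pair {sorted(key)} under duplicate_policy='error'"
                )
            report.n_merged_duplicates += 1
            if rec.score > prev.score:
                best[key] = rec

    for rec in best.values():
        graph._add_edge(rec)
    report.n_edges = graph.n_edges
    if report.n_dropped_whitelist or report.n_merged_duplicates:
        logger.info(
            "build_graph: %d records in, %d dropped by whitelist, %d duplicates merged, %d edges",
            report.n_input,
            report.n_dropped_whitelist,
            report.n_merged_duplicates,
            report.n_edges,
        )
    return graph


def node_partition(graph: HybridGraph) -> tuple[set[NodeRef], set[NodeRef]]:
    """Split the node set into (proteins, chemicals).

    The two sets are disjoint and their union is the full node set; needed
    by the stratified null-set sampling of the permutation test.
    """
    proteins = {r for r in graph.nodes() if r.kind == PROTEIN}
    chemicals = {r for r in graph.nodes() if r.kind == CHEMICAL}
    return proteins, chemicals


# -- edge-list caching -------------------------------------------------

EDGELIST_HEADER = ("node1", "kind1", "node2", "kind2", "score")


def write_edgelist(graph: HybridGraph, path) -> None:
    """Dump the graph as a 5-column TSV (node1, kind1, node2, kind2, score)."""
    with open(path, "w") as fh:
        fh.write("\t".join(EDGELIST_HEADER) + "\n")
        for rec in graph.to_records():
            fh.write(f"{rec.a.id}\t{rec.a.kind}\t{rec.b.id}\t{rec.b.kind}\t{rec.score}\n")


def read_edgelist(path) -> HybridGraph:
    """Restore a graph written by :func:`write_edgelist`."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != EDGELIST_HEADER:
            raise ValidationError(f"unexpected edge-list header: {header}")
        for line in fh:
            if not line.strip():
                continue
            n1, k1, n2, k2, score = line.rstrip("\n").split("\t")
            records.append(InteractionRecord(NodeRef(n1, k1), NodeRef(n2, k2), int(score)))
    return build_graph(records, duplicate_policy="error")
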