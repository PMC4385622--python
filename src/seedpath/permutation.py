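"""Permutation null and per-candidate permutation FDR.

The null distribution is built from randomly drawn seed sets of matched
composition: each null set contains exactly as many protein nodes and as
many chemical nodes as the *mapped* true seed set, sampled uniformly
without replacement from all graph nodes of each class (true seeds are
not excluded).  For each candidate, the permutation FDR is

    fdr(v) = #{null sets whose betweenness of v beats the observed} / N

with N the number of permutations.  The default comparator is strict
(null "larger than" observed); ``greater_or_equal`` is offered as the
conventional permutation-p alternative -- the two differ only on ties.
Despite the historical name, this quantity is a per-node permutation
p-value, not a false-discovery-rate estimate; outputs keep the "fdr"
column name.

Sampling protocol (fixed so that independent implementations can replay
the same stream): one ``numpy.random.Generator`` is seeded from
``rng_seed``; for each permutation in order, one ``rng.choice`` call
draws the protein ids from the ascending-sorted protein list, then one
draws the chemical ids from the ascending-sorted chemical list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .betweenness import (
    BetweennessTable,
    CandidateList,
    CandidateRecord,
    SeedSet,
    seed_betweenness,
)
from .errors import DomainError
from .graph import CHEMICAL, PROTEIN, HybridGraph, NodeRef

logger = logging.getLogger(__name__)

COMPARATORS = ("strictly_greater", "greater_or_equal")


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation test.

    ``n_permutations`` defaults to 1000 null sets and ``threshold`` to
    0.05, the conventional operating point; the FDR granularity is
    1/n_permutations.
    """

    n_permutations: int = 1000
    rng_seed: int = 0
    comparator: str = "strictly_greater"
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise DomainError("n_permutations must be >= 1")
        if not (0.0 < self.threshold < 1.0):
            raise DomainError("threshold must lie strictly between 0 and 1")
        if self.comparator not in COMPARATORS:
            raise DomainError(f"comparator must be one of {COMPARATORS}, got {self.comparator!r}")


def sample_null_seed_set(
    graph: HybridGraph,
    n_genes: int,
    n_chems: int,
    rng: np.random.Generator,
) -> SeedSet:
    """Draw one composition-matched random seed set.

    Exactly ``n_genes`` protein nodes and ``n_chems`` chemical nodes,
    uniform without replacement within each class.  Successive calls on
    the same generator yield independent sets.
    """
    proteins = graph.ids_of_kind(PROTEIN)
    chemicals = graph.ids_of_kind(CHEMICAL)
    if n_genes > len(proteins):
        raise DomainError(f"requested {n_genes} protein seeds but graph has {len(proteins)}")
    if n_chems > len(chemicals):
        raise DomainError(f"requested {n_chems} chemical seeds but graph has {len(chemicals)}")
    genes = tuple(
        NodeRef(i, PROTEIN) for i in rng.choice(proteins, size=n_genes, replace=False)
    ) if n_genes else ()
    chems = tuple(
        NodeRef(i, CHEMICAL) for i in rng.choice(chemicals, size=n_chems, replace=False)
    ) if n_chems else ()
    return SeedSet(genes, chems)


def permutation_fdr(
    graph: HybridGraph,
    observed: BetweennessTable,
    candidates: Sequence[CandidateRecord],
    n_genes: int,
    n_chems: int,
    config: PermutationConfig,
    mode: str = "single_path",
) -> list[CandidateRecord]:
    """Assign a permutation FDR to every candidate.

    Runs the seed-restricted betweenness on ``config.n_permutations``
    null sets (matched to the *mapped* true-seed composition
    ``n_genes``/``n_chems``) under the same path mode as the observed
    run, and counts for each candidate how many null sets beat its
    observed betweenness.  Null betweenness is only tracked for the
    candidate nodes.  The whole computation is reproducible from
    ``config.rng_seed``; output order matches input order.
    """
    if mode != observed.mode:
        raise DomainError(
            f"path-mode mismatch: observed table was computed in {observed.mode!r}, "
            f"null runs requested in {mode!r}"
        )
    rng = np.random.default_rng(config.rng_seed)
    strict = config.comparator == "strictly_greater"

    obs = np.array([observed.count(rec.node) for rec in candidates], dtype=np.int64)
    nodes = [rec.node for rec in candidates]
    exceed = np.zeros(len(candidates), dtype=np.int64)

    for _ in range(config.n_permutations):
        null_set = sample_null_seed_set(graph, n_genes, n_chems, rng)
        table = seed_betweenness(graph, null_set, mode=mode)
        null = np.array([table.count(n) for n in nodes], dtype=np.int64)
        exceed += (null > obs) if strict else (null >= obs)

    out: list[CandidateRecord] = []
    for rec, e in zip(candidates, exceed):
        out.append(
            CandidateRecord(
                rec.node,
                rec.betweenness,
                fdr=float(e) / config.n_permutations,
                exceed_count=int(e),
            )
        )
    return out


def filter_significant(
    candidates: Sequence[CandidateRecord],
    threshold: float = 0.05,
) -> list[CandidateRecord]:
    """Candidates with FDR *strictly* smaller than the threshold.

    Relative order is preserved; an FDR exactly equal to the threshold is
    excluded.
    """
    for rec in candidates:
        if rec.fdr is None:
            raise DomainError(f"candidate {rec.node.id!r} has no FDR assigned")
    return [rec for rec in candidates if rec.fdr < threshold]
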