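"""Model/Results interface over the prioritization procedure.

:class:`SeedBetweennessModel` bundles a hybrid graph with the known
disease seed lists; its :meth:`~SeedBetweennessModel.fit` runs the whole
procedure -- seed mapping, all-seed-pair shortest paths, candidate
selection, permutation null -- and returns a
:class:`PrioritizationResults` carrying the candidate table (betweenness
+ permutation FDR), the significant subset, run diagnostics and a
``summary()`` report.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import io as spio
from .betweenness import (
    BetweennessTable,
    CandidateList,
    CandidateRecord,
    SeedSet,
    map_seeds,
    seed_betweenness,
    select_candidates,
)
from .errors import DomainError
from .graph import CHEMICAL, PROTEIN, HybridGraph, build_graph
from .permutation import PermutationConfig, filter_significant, permutation_fdr


@dataclass
class RunSummary:
    """Size and tally diagnostics of one full run."""

    n_nodes: int
    n_edges: int
    n_seed_genes_mapped: int
    n_seed_chems_mapped: int
    n_seeds_unmapped: int
    n_pairs_evaluated: int
    n_pairs_disconnected: int
    n_candidates_genes: int
    n_candidates_chems: int
    n_significant_genes: int
    n_significant_chems: int
    config: dict

    def as_text(self) -> str:
        lines = ["run summary", "-----------"]
        for key in (
            "n_nodes", "n_edges",
            "n_seed_genes_mapped", "n_seed_chems_mapped", "n_seeds_unmapped",
            "n_pairs_evaluated", "n_pairs_disconnected",
            "n_candidates_genes", "n_candidates_chems",
            "n_significant_genes", "n_significant_chems",
        ):
            lines.append(f"{key}\t{getattr(self, key)}")
        lines.append("config")
        for k in sorted(self.config):
            lines.append(f"  {k}\t{self.config[k]}")
        return "\n".join(lines) + "\n"


class SeedBetweennessModel:
    """Seed-restricted betweenness prioritization on a hybrid graph.

    Parameters
    ----------
    graph
        The weighted hybrid interaction graph.
    seed_genes, seed_chemicals
        Identifiers of the known disease genes and chemicals; matched
        against graph nodes by exact string equality.
    path_mode
        ``"single_path"`` (default, one deterministic lexicographically
        tie-broken shortest path per seed pair) or ``"all_paths"``.
    include_seeds
        Whether seed nodes with positive betweenness are retained among
        the candidates (default False: candidates are new nodes only).
    """

    def __init__(
        self,
        graph: HybridGraph,
        seed_genes: Sequence[str],
        seed_chemicals: Sequence[str] = (),
        path_mode: str = "single_path",
        include_seeds: bool = False,
    ) -> None:
        self.graph = graph
        self.seed_gene_ids = list(seed_genes)
        self.seed_chemical_ids = list(seed_chemicals)
        self.path_mode = path_mode
        self.include_seeds = include_seeds
        self.seeds: SeedSet = map_seeds(graph, self.seed_gene_ids, self.seed_chemical_ids)

    @classmethod
    def from_tables(
        cls,
        seed_genes,
        seed_chemicals=None,
        pp=None,
        cc=None,
        cp=None,
        whitelist=None,
        duplicate_policy: str = "max",
        **kwargs,
    ) -> "SeedBetweennessModel":
        """Build the model straight from interaction-table and seed files.

        ``pp``/``cc``/``cp`` are paths to the three dialect tables (any
        subset may be omitted); ``seed_genes``/``seed_chemicals`` are
        one-id-per-line files; ``whitelist`` optionally restricts the
        chemical space.
        """
        records = []
        for source, dialect in ((pp, "pp"), (cc, "cc"), (cp, "cp")):
            if source is not None:
                records.extend(spio.read_interaction_table(source, dialect))
        if not records:
            raise DomainError("no interaction tables supplied")
        wl = spio.read_whitelist(whitelist) if whitelist is not None else None
        graph = build_graph(records, chemical_whitelist=wl, duplicate_policy=duplicate_policy)
        gene_ids = [r.id for r in spio.read_seed_list(seed_genes, PROTEIN)]
        chem_ids = (
            [r.id for r in spio.read_seed_list(seed_chemicals, CHEMICAL)]
            if seed_chemicals is not None
            else []
        )
        return cls(graph, gene_ids, chem_ids, **kwargs)

    def fit(
        self,
        n_permutations: int = 1000,
        rng_seed: int = 0,
        comparator: str = "strictly_greater",
        threshold: float = 0.05,
    ) -> "PrioritizationResults":
        """Run betweenness + permutation test; return the results object."""
        config = PermutationConfig(
            n_permutations=n_permutations,
            rng_seed=rng_seed,
            comparator=comparator,
            threshold=threshold,
        )
        table = seed_betweenness(self.graph, self.seeds, mode=self.path_mode)
        candidates = select_candidates(table, self.seeds, include_seeds=self.include_seeds)
        scored = permutation_fdr(
            self.graph,
            table,
            candidates,
            n_genes=self.seeds.n_genes,
            n_chems=self.seeds.n_chems,
            config=config,
            mode=self.path_mode,
        )
        return PrioritizationResults(self, table, scored, candidates.seed_hits, config)


class PrioritizationResults:
    """Fitted prioritization: candidate table, FDRs and diagnostics."""

    def __init__(
        self,
        model: SeedBetweennessModel,
        betweenness_table: BetweennessTable,
        candidates: list[CandidateRecord],
        seed_hits: list[CandidateRecord],
        config: PermutationConfig,
    ) -> None:
        self.model = model
        self.betweenness_table = betweenness_table
        self.candidate_records = candidates
        self.seed_hits = seed_hits
        self.config = config

    # -- tabular views --------------------------------------------------

    @staticmethod
    def _frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.node.id for r in records],
                "kind": [r.node.kind for r in records],
                "betweenness": [r.betweenness for r in records],
                "exceed_count": [r.exceed_count for r in records],
                "fdr": [r.fdr for r in records],
            }
        )

    @property
    def candidates(self) -> pd.DataFrame:
        """All candidates (betweenness > 0) with permutation FDRs."""
        return self._frame(self.candidate_records)

    def significant_records(self, threshold: Optional[float] = None) -> list[CandidateRecord]:
        return filter_significant(
            self.candidate_records,
            self.config.threshold if threshold is None else threshold,
        )

    def significant(self, threshold: Optional[float] = None) -> pd.DataFrame:
        """Candidates with FDR strictly below the threshold."""
        return self._frame(self.significant_records(threshold))

    # -- diagnostics ----------------------------------------------------

    def _tally(self, records: Sequence[CandidateRecord], kind: str) -> int:
        return sum(1 for r in records if r.node.kind == kind)

    def run_summary(self) -> RunSummary:
        sig = self.significant_records()
        seeds = self.model.seeds
        return RunSummary(
            n_nodes=self.model.graph.n_nodes,
            n_edges=self.model.graph.n_edges,
            n_seed_genes_mapped=seeds.n_genes,
            n_seed_chems_mapped=seeds.n_chems,
            n_seeds_unmapped=len(seeds.unmapped),
            n_pairs_evaluated=self.betweenness_table.pairs_evaluated,
            n_pairs_disconnected=self.betweenness_table.pairs_disconnected,
            n_candidates_genes=self._tally(self.candidate_records, PROTEIN),
            n_candidates_chems=self._tally(self.candidate_records, CHEMICAL),
            n_significant_genes=self._tally(sig, PROTEIN),
            n_significant_chems=self._tally(sig, CHEMICAL),
            config={
                "n_permutations": self.config.n_permutations,
                "rng_seed": self.config.rng_seed,
                "comparator": self.config.comparator,
                "threshold": self.config.threshold,
                "path_mode": self.model.path_mode,
                "include_seeds": self.model.include_seeds,
            },
        )

    def summary(self) -> str:
        """Human-readable report: sizes, tallies and the top candidates."""
        s = self.run_summary()
        buf = _io.StringIO()
        buf.write(s.as_text())
        top = self.candidates.head(10)
        if len(top):
            buf.write("\ntop candidates (by betweenness)\n")
            buf.write(top.to_string(index=False))
            buf.write("\n")
        return buf.getvalue()

    # -- output files ---------------------------------------------------

    def write_tables(self, out_dir) -> None:
        """Write candidates.tsv, significant.tsv and summary.txt."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        spio.write_candidate_table(self.candidate_records, out_dir / "candidates.tsv")
        spio.write_candidate_table(self.significant_records(), out_dir / "significant.tsv")
        (out_dir / "summary.txt").write_text(self.run_summary().as_text())
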