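"""End-to-end pipeline: files in, candidate tables and a run summary out.

The pipeline wires the stages read -> build_graph -> map_seeds ->
seed_betweenness -> select_candidates -> permutation_fdr ->
filter_significant, writing ``candidates.tsv`` (all nodes with positive
betweenness, with FDRs), ``significant.tsv`` (FDR strictly below the
threshold) and ``summary.txt``.  All randomness flows from the single
configured rng seed, so outputs are exactly reproducible from
(inputs, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

from .errors import FormatError, SeedPathError
from .model import RunSummary, SeedBetweennessModel

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one run.

    File-based configuration uses simple ``key = value`` (or
    ``key: value``) lines; command-line flags override file values.
    """

    pp: Optional[str] = None
    cc: Optional[str] = None
    cp: Optional[str] = None
    seed_genes: Optional[str] = None
    seed_chemicals: Optional[str] = None
    whitelist: Optional[str] = None
    out_dir: str = "seedpath_out"
    n_permutations: int = 1000
    rng_seed: int = 0
    threshold: float = 0.05
    path_mode: str = "single_path"
    comparator: str = "strictly_greater"
    include_seeds: bool = False

    _TYPES = {
        "n_permutations": int,
        "rng_seed": int,
        "threshold": float,
        "include_seeds": lambda v: str(v).strip().lower() in ("1", "true", "yes"),
    }

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                for sep in ("=", ":"):
                    if sep in line:
                        key, _, raw = line.partition(sep)
                        break
                else:
                    raise FormatError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
                key, raw = key.strip(), raw.strip()
                if key not in known:
                    raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
                values[key] = cls._TYPES.get(key, str)(raw)
        return cls(**values)

    def override(self, **kwargs) -> "PipelineConfig":
        """New config with the non-None keyword values applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute the full procedure described by ``config``.

    Returns the run summary; the candidate, significant and summary files
    are written under ``config.out_dir``.  Stage failures are re-raised
    with the stage name prepended, and partial outputs are removed.
    """
    if config.seed_genes is None and config.seed_chemicals is None:
        raise SeedPathError("config must name at least one seed list")

    stage = "read+build"
    try:
        model = SeedBetweennessModel.from_tables(
            seed_genes=config.seed_genes,
            seed_chemicals=config.seed_chemicals,
            pp=config.pp,
            cc=config.cc,
            cp=config.cp,
            whitelist=config.whitelist,
            path_mode=config.path_mode,
            include_seeds=config.include_seeds,
        )
        logger.info(
            "graph: %d nodes, %d edges; seeds mapped: %d genes, %d chemicals (%d unmapped)",
            model.graph.n_nodes, model.graph.n_edges,
            model.seeds.n_genes, model.seeds.n_chems, len(model.seeds.unmapped),
        )
        stage = "betweenness+permutation"
        results = model.fit(
            n_permutations=config.n_permutations,
            rng_seed=config.rng_seed,
            comparator=config.comparator,
            threshold=config.threshold,
        )
        stage = "write"
        out_dir = Path(config.out_dir)
        try:
            results.write_tables(out_dir)
        except Exception:
            for name in ("candidates.tsv", "significant.tsv", "summary.txt"):
                (out_dir / name).unlink(missing_ok=True)
            raise
    except SeedPathError as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    summary = results.run_summary()
    logger.info(
        "candidates: %d genes + %d chemicals; significant at %g: %d genes + %d chemicals",
        summary.n_candidates_genes, summary.n_candidates_chems, config.threshold,
        summary.n_significant_genes, summary.n_significant_chems,
    )
    return summary
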