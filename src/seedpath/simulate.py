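"""Synthetic interaction tables with a planted-linker ground truth.

The generator emulates the structure of STRING/STITCH-style inputs: two
node classes (proteins, chemicals), Erdős–Rényi background edges within
and between the classes with uniform integer scores, and an optional
planted signal -- "linker" nodes wired to several seed nodes with
high-score (hence low-weight) edges, so that each linker lies on a cheap
two-hop route between seed pairs.  Because the linker score range sits
strictly above the background range, linker routes (weight at most
2*(1000 - linker_min)) undercut any background route, making the linkers
recoverable ground truth for the full prioritization pipeline.

The defaults define the reference benchmark instance: an 80-node network
(60 proteins, 20 chemicals) at background density 0.05 with weak
background scores 150-400, 11 seeds (8 genes + 3 chemicals) and 5
planted linkers wired at scores 900-990.  No attempt is made to match
the degree or score distribution of real interaction databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import DomainError, ValidationError
from .graph import CHEMICAL, PROTEIN, SCORE_MAX, SCORE_MIN, InteractionRecord, NodeRef
from .io import write_interaction_table

TRUTH_KEYS = ("seed_genes", "seed_chemicals", "linkers", "decoys")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic instance; defaults are the reference
    benchmark conditions."""

    n_proteins: int = 60
    n_chemicals: int = 20
    background_edge_prob: float = 0.05
    background_score_range: tuple[int, int] = (150, 400)
    n_seed_genes: int = 8
    n_seed_chems: int = 3
    n_linkers: int = 5
    linker_score_range: tuple[int, int] = (900, 990)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.background_score_range, self.linker_score_range):
            if not (SCORE_MIN <= lo <= hi <= SCORE_MAX):
                raise DomainError(f"score range ({lo}, {hi}) must lie within [1, 999]")
        if self.n_linkers and self.linker_score_range[0] <= self.background_score_range[1]:
            raise DomainError(
                "linker score range must sit strictly above the background range "
                "(linker edges must have strictly smaller weights)"
            )
        if not (0.0 <= self.background_edge_prob <= 1.0):
            raise DomainError("background_edge_prob must lie in [0, 1]")
        if self.n_seed_genes > self.n_proteins or self.n_seed_chems > self.n_chemicals:
            raise DomainError("seed counts exceed node totals")
        n_nonseed = (self.n_proteins - self.n_seed_genes) + (self.n_chemicals - self.n_seed_chems)
        if self.n_linkers > n_nonseed:
            raise DomainError("too few non-seed nodes to host the linkers")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of one instance: the three groups are disjoint."""

    seed_genes: tuple[str, ...]
    seed_chemicals: tuple[str, ...]
    linker_ids: tuple[str, ...]
    decoy_ids: tuple[str, ...]

    @property
    def seed_ids(self) -> tuple[str, ...]:
        return self.seed_genes + self.seed_chemicals


def _node_ids(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    chemicals = [f"C{i:04d}" for i in range(spec.n_chemicals)]
    return proteins, chemicals


def _ref(node_id: str) -> NodeRef:
    return NodeRef(node_id, PROTEIN if node_id.startswith("P") else CHEMICAL)


def generate_background(spec: SyntheticSpec, rng: np.random.Generator) -> list[InteractionRecord]:
    """Erdős–Rényi background over the pooled node set.

    Each unordered node pair (within or between classes) independently
    becomes an interaction with probability ``background_edge_prob``;
    scores are uniform integers on ``background_score_range``.  Each pair
    appears at most once (pre-deduplicated output).
    """
    proteins, chemicals = _node_ids(spec)
    nodes = proteins + chemicals
    lo, hi = spec.background_score_range
    records: list[InteractionRecord] = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if rng.random() < spec.background_edge_prob:
                score = int(rng.integers(lo, hi + 1))
                records.append(InteractionRecord(_ref(nodes[i]), _ref(nodes[j]), score))
    return records


def plant_linkers(
    background: list[InteractionRecord],
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[list[InteractionRecord], PlantedTruth]:
    """Designate seeds, wire linker nodes to them, return records + truth.

    Seeds are drawn uniformly from each class.  Each of the ``n_linkers``
    linker nodes (drawn from the non-seed nodes, both classes pooled) is
    wired to at least two randomly chosen seeds with scores from
    ``linker_score_range``, so it lies on a low-weight route between at
    least one seed pair.  Remaining non-seed, non-linker nodes are the
    decoys.  Linker edges replace any background edge on the same pair
    (they carry the higher score, so a max-merge keeps them too).
    """
    proteins, chemicals = _node_ids(spec)
    seed_genes = tuple(sorted(rng.choice(proteins, size=spec.n_seed_genes, replace=False))) if spec.n_seed_genes else ()
    seed_chems = tuple(sorted(rng.choice(chemicals, size=spec.n_seed_chems, replace=False))) if spec.n_seed_chems else ()
    seed_ids = set(seed_genes) | set(seed_chems)
    non_seed = sorted(set(proteins + chemicals) - seed_ids)
    linkers = tuple(sorted(rng.choice(non_seed, size=spec.n_linkers, replace=False))) if spec.n_linkers else ()
    decoys = tuple(n for n in non_seed if n not in set(linkers))

    seeds_sorted = sorted(seed_ids)
    n_wire = min(3, len(seeds_sorted))
    if spec.n_linkers and n_wire < 2:
        raise DomainError("need at least 2 seeds to wire a linker")

    records = {rec.key: rec for rec in background}
    lo, hi = spec.linker_score_range
    for linker in linkers:
        targets = rng.choice(seeds_sorted, size=n_wire, replace=False)
        for seed in targets:
            score = int(rng.integers(lo, hi + 1))
            rec = InteractionRecord(_ref(linker), _ref(seed), score)
            records[rec.key] = rec

    truth = PlantedTruth(seed_genes, seed_chems, linkers, decoys)
    return list(records.values()), truth


def generate_instance(spec: SyntheticSpec) -> tuple[list[InteractionRecord], PlantedTruth]:
    """Background + planted linkers from the spec's own rng seed."""
    rng = np.random.default_rng(spec.rng_seed)
    background = generate_background(spec, rng)
    return plant_linkers(background, spec, rng)


# -- fixture files -----------------------------------------------------


def write_fixture(records: list[InteractionRecord], truth: PlantedTruth, directory) -> None:
    """Write one instance as pp/cc/cp tables, seed lists and a truth manifest.

    Records are partitioned into the three dialect files by endpoint
    kinds; re-reading with the table reader reproduces them exactly.
    Empty classes yield header-only files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_class = {"pp": [], "cc": [], "cp": []}
    for rec in records:
        by_class[rec.interaction_class].append(rec)
    for dialect, recs in by_class.items():
        write_interaction_table(recs, directory / f"{dialect}.tsv", dialect)
    (directory / "seed_genes.txt").write_text("".join(f"{s}\n" for s in truth.seed_genes))
    (directory / "seed_chemicals.txt").write_text("".join(f"{s}\n" for s in truth.seed_chemicals))
    with open(directory / "truth.txt", "w") as fh:
        for key, ids in zip(
            TRUTH_KEYS,
            (truth.seed_genes, truth.seed_chemicals, truth.linker_ids, truth.decoy_ids),
        ):
            fh.write(f"{key}\t{','.join(ids)}\n")


def read_truth(path) -> PlantedTruth:
    """Read a truth manifest written by :func:`write_fixture`."""
    fields: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            key, _, joined = line.rstrip("\n").partition("\t")
            fields[key] = tuple(joined.split(",")) if joined else ()
    missing = set(TRUTH_KEYS) - set(fields)
    if missing:
        raise ValidationError(f"truth manifest missing keys: {sorted(missing)}")
    return PlantedTruth(
        fields["seed_genes"], fields["seed_chemicals"], fields["linkers"], fields["decoys"]
    )
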