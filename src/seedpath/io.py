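"""Readers and writers for STRING/STITCH-dialect tables and seed lists.

Input tables are header-led, tab- or whitespace-separated, and come in
three dialects named after the endpoint kinds: ``pp`` (protein-protein,
STRING protein.links), ``cc`` (chemical-chemical, STITCH
chemical_chemical.links) and ``cp`` (chemical-protein, STITCH
protein_chemical.links).  Both the full multi-score layouts and a minimal
3-column (id, id, combined_score) layout are accepted; the combined score
is selected by header name.  Identifiers are treated as opaque strings --
no namespace parsing or zero-padding normalization is attempted.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

from .errors import DomainError, FormatError, ValidationError
from .graph import CHEMICAL, PROTEIN, SCORE_MAX, SCORE_MIN, InteractionRecord, NodeRef

logger = logging.getLogger(__name__)

Source = Union[str, Path, IO[str], Iterable[str]]

DIALECT_KINDS = {
    "pp": (PROTEIN, PROTEIN),
    "cc": (CHEMICAL, CHEMICAL),
    "cp": (CHEMICAL, PROTEIN),
}

#: channel sub-score column names recognised in STITCH layouts
CHANNEL_COLUMNS = ("similarity", "experiment", "experimental", "database", "textmining", "prediction")

_SPLIT = re.compile(r"[ \t]+")


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def read_interaction_table(
    source: Source,
    dialect: str,
    score_column: Optional[str] = None,
) -> list[InteractionRecord]:
    """Read one interaction table into scored records.

    Parameters
    ----------
    source
        Path or iterable of lines; the first line is the header.
    dialect
        ``"pp"``, ``"cc"`` or ``"cp"``; fixes the endpoint kinds (for
        ``cp`` the first column is the chemical, the second the protein).
    score_column
        Column holding the integer combined score.  Defaults to the column
        named ``combined_score`` (case-insensitive); if absent and the
        table has exactly three columns, the third column is used.

    Raises
    ------
    FormatError
        Missing score column, or a malformed line (wrong field count,
        non-integer score) -- the message carries the line number.
    ValidationError
        A score outside [1, 999].  0 encodes "no interaction" in the
        source databases and must never appear as a row.
    """
    if dialect not in DIALECT_KINDS:
        raise DomainError(f"dialect must be one of {sorted(DIALECT_KINDS)}, got {dialect!r}")
    kind_a, kind_b = DIALECT_KINDS[dialect]

    lines = _iter_lines(source)
    try:
        header_line = next(lines)
    except StopIteration:
        raise FormatError("empty input: no header line") from None
    columns = _SPLIT.split(header_line.strip())
    if len(columns) < 3:
        raise FormatError(f"header must name at least 3 columns, got {columns}")

    lower = [c.lower() for c in columns]
    if score_column is not None:
        if score_column not in columns:
            raise FormatError(f"score column {score_column!r} not in header {columns}")
        score_idx = columns.index(score_column)
    elif "combined_score" in lower:
        score_idx = lower.index("combined_score")
    elif len(columns) == 3:
        score_idx = 2
    else:
        raise FormatError(
            f"no 'combined_score' column in header {columns}; pass score_column explicitly"
        )

    channel_idx = {
        columns[i]: i
        for i, name in enumerate(lower)
        if name in CHANNEL_COLUMNS and i not in (0, 1, score_idx)
    }

    records: list[InteractionRecord] = []
    for lineno, line in enumerate(lines, start=2):
        if not line.strip():
            continue
        fields = _SPLIT.split(line.strip())
        if len(fields) != len(columns):
            raise FormatError(
                f"line {lineno}: expected {len(columns)} fields, got {len(fields)}"
            )
        try:
            score = int(fields[score_idx])
        except ValueError:
            raise FormatError(f"line {lineno}: score {fields[score_idx]!r} is not an integer") from None
        if not (SCORE_MIN <= score <= SCORE_MAX):
            raise ValidationError(
                f"line {lineno}: score {score} outside [{SCORE_MIN}, {SCORE_MAX}] "
                "(0 encodes 'no interaction' and must not appear as a row)"
            )
        channels = None
        if channel_idx:
            try:
                channels = {name: int(fields[i]) for name, i in channel_idx.items()}
            except ValueError:
                channels = None
        records.append(
            InteractionRecord(
                NodeRef(fields[0], kind_a), NodeRef(fields[1], kind_b), score, channels
            )
        )
    return records


def read_seed_list(source: Source, kind: str) -> list[NodeRef]:
    """Read a one-identifier-per-line seed (or whitelist) file.

    Blank lines and ``#`` comments are skipped.  Duplicates are dropped,
    keeping first-seen order; the duplicate count is logged.  An empty
    result is an error -- a seed set must be non-empty.
    """
    if kind not in (PROTEIN, CHEMICAL):
        raise DomainError(f"kind must be 'protein' or 'chemical', got {kind!r}")
    seen: dict[str, None] = {}
    n_dupes = 0
    for line in _iter_lines(source):
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        if token in seen:
            n_dupes += 1
        else:
            seen[token] = None
    if not seen:
        raise ValidationError("seed list is empty")
    if n_dupes:
        logger.info("read_seed_list: %d duplicate entries dropped (%d distinct)", n_dupes, len(seen))
    return [NodeRef(tok, kind) for tok in seen]


def read_whitelist(source: Source) -> set[str]:
    """Read a chemical whitelist (one identifier per line) into a set."""
    return {r.id for r in read_seed_list(source, CHEMICAL)}


def write_candidate_table(records: Sequence, sink: Union[str, Path, IO[str]]) -> None:
    """Write candidates as TSV: ``id  kind  betweenness  fdr``.

    Rows are sorted by descending betweenness, ties broken by ascending
    id; FDR is printed with 3 decimals (the granularity of a
    1000-permutation test), or ``NA`` when not yet assigned.
    """
    def _emit(fh: IO[str]) -> None:
        fh.write("id\tkind\tbetweenness\tfdr\n")
        ordered = sorted(records, key=lambda r: (-r.betweenness, r.node.id))
        for rec in ordered:
            fdr = "NA" if rec.fdr is None else f"{rec.fdr:.3f}"
            fh.write(f"{rec.node.id}\t{rec.node.kind}\t{rec.betweenness}\t{fdr}\n")

    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            _emit(fh)
    else:
        _emit(sink)


def write_interaction_table(records: Iterable[InteractionRecord], sink: Union[str, Path, IO[str]], dialect: str) -> None:
    """Write records in the minimal 3-column layout for one dialect."""
    headers = {
        "pp": ("protein1", "protein2", "combined_score"),
        "cc": ("chemical1", "chemical2", "combined_score"),
        "cp": ("chemical", "protein", "combined_score"),
    }
    if dialect not in headers:
        raise DomainError(f"dialect must be one of {sorted(headers)}, got {dialect!r}")
    kind_a, kind_b = DIALECT_KINDS[dialect]

    def _emit(fh: IO[str]) -> None:
        fh.write("\t".join(headers[dialect]) + "\n")
        for rec in records:
            a, b = rec.a, rec.b
            if (a.kind, b.kind) == (kind_b, kind_a) and kind_a != kind_b:
                a, b = b, a
            if (a.kind, b.kind) != (kind_a, kind_b):
                raise ValidationError(
                    f"record {a.id}-{b.id} has kinds ({a.kind}, {b.kind}), "
                    f"not writable in dialect {dialect!r}"
                )
            fh.write(f"{a.id}\t{b.id}\t{rec.score}\n")

    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            _emit(fh)
    else:
        _emit(sink)
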