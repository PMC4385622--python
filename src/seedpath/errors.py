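"""Exception hierarchy shared across the package."""


class SeedPathError(Exception):
    """Base class for all package errors."""


class FormatError(SeedPathError):
    """A table or config file does not have the expected shape (missing
    columns, malformed lines).  Carries a line number where applicable."""


class ValidationError(SeedPathError):
    """A record violates a domain invariant (e.g. score outside [1, 999])."""


class GraphConstructionError(SeedPathError):
    """The interaction set cannot form a valid hybrid graph (kind conflicts,
    forbidden duplicates)."""


class DomainError(SeedPathError):
    """An operation was called outside its precondition (bad score, missing
    node, source == target, too few seeds)."""
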