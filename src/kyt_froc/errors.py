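"""Exception hierarchy for the kyt_froc package."""


class KytFrocError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(KytFrocError):
    """A file does not conform to the documented schema (missing or
    malformed field); the message names the offending field/record."""


class ValidationError(KytFrocError):
    """Structurally well-formed data violates a domain invariant
    (duplicate identifier, rating out of range, circle out of bounds...)."""


class ContractError(KytFrocError):
    """An operation was called outside its precondition."""


class UndefinedQuantityError(KytFrocError):
    """A requested quantity has a zero denominator (no hazard points,
    no normal scenes, no events)."""


class GenerationError(KytFrocError):
    """The synthetic generator could not satisfy its geometric
    constraints (e.g. non-overlapping circle placement) within the
    retry budget."""
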