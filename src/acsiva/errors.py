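"""Exception hierarchy for acsiva."""


class AcsivaError(Exception):
    """Base class for all acsiva errors."""


class SchemaError(AcsivaError):
    """Input table does not match the expected schema."""


class ParseError(AcsivaError):
    """A cell or file could not be parsed."""


class DataError(AcsivaError):
    """Input data violate an invariant (duplicate ids, orphan sites, ...)."""


class DomainError(AcsivaError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class StructureError(AcsivaError):
    """A tree or linear system is structurally degenerate."""
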