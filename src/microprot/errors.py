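"""Exception hierarchy shared across the pipeline stages."""


class MicroprotError(Exception):
    """Base class for all package errors."""


class SchemaError(MicroprotError):
    """A table is missing a required column or uses an unknown layout."""


class ValidationError(MicroprotError):
    """Values violate an invariant (negative counts, duplicate accessions, ...)."""


class StageOrderError(MicroprotError):
    """An operation was requested before its prerequisite stage ran."""
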