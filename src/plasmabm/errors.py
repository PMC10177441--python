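"""Exceptions raised by table readers and validators."""


class SchemaError(ValueError):
    """A required column is missing or a table is structurally malformed."""


class CohortValidationError(ValueError):
    """A record violates a domain invariant (bad VAF, duplicate ID, ...)."""
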