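"""Exception hierarchy for QC input and validation failures."""


class QCError(Exception):
    """Base class for all errors raised by taskfmri_qc."""


class SchemaError(QCError):
    """A required column or field is missing from an input table."""


class ParseError(QCError):
    """A cell could not be parsed as the expected type."""


class ValidationError(QCError):
    """Input values violate a documented precondition or invariant."""
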