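"""Exception types shared across the pipeline."""


class ChillClassError(Exception):
    """Base class for all package errors."""


class DomainError(ChillClassError, ValueError):
    """A value violates a mathematical or physical precondition.

    The message always names the offending quantity so that malformed
    instrument exports can be traced back to a column.
    """


class SchemaError(ChillClassError, ValueError):
    """A CSV is missing required columns or has unparseable rows."""
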