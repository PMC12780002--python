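"""Exception hierarchy.

``NeurocodeError`` is the root; subclasses distinguish configuration
mistakes (``ConfigError``), on-disk schema problems (``SchemaError``),
truncated/inconsistent binaries (``CorruptFileError``), malformed text rows
(``ParseError``), and invalid data values (``ValidationError``) so that the
CLI can map them onto distinct exit codes.
"""


class NeurocodeError(Exception):
    """Base class for all package errors."""


class ConfigError(NeurocodeError):
    """A parameter or configuration value is invalid."""


class SchemaError(NeurocodeError):
    """A file is missing required fields or has an unknown format version."""


class CorruptFileError(NeurocodeError):
    """Binary payload inconsistent with its sidecar metadata."""


class ParseError(NeurocodeError):
    """A text table row could not be parsed; carries the row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ValidationError(NeurocodeError):
    """Data violates a declared invariant (e.g. negative cell count)."""
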