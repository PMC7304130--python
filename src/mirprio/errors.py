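"""Exception hierarchy shared across the pipeline stages."""


class MirprioError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirprioError):
    """A whole input file violates its expected layout (missing column, bad GMT line)."""


class RowError(MirprioError):
    """A single record in an otherwise well-formed table is invalid.

    Carries the zero-based row index so callers can point at the offending line.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class PreconditionError(MirprioError):
    """An operation was called on inputs that violate its stated preconditions."""
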