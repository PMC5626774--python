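"""Exception hierarchy."""


class CodresError(Exception):
    """Base class for all errors raised by this package."""


class InvalidRecordError(CodresError):
    """A domain object violates one of its invariants."""


class TableParseError(CodresError):
    """A delimited input table is malformed.

    Carries the 1-based row number (header = row 1) when the offending
    row is known.
    """

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)
        self.row = row
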