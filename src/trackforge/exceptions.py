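"""Exception hierarchy for trackforge."""


class TrackforgeError(Exception):
    """Base class for all trackforge errors."""


class ValidationError(TrackforgeError):
    """Input data or configuration violates an invariant."""


class FormatError(ValidationError):
    """A required column is missing or a file is not in the expected layout."""


class ParseError(ValidationError):
    """A cell value could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
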