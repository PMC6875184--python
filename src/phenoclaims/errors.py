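"""Exception hierarchy for dataset loading and validation."""


class PhenoclaimsError(Exception):
    """Base class for all package errors."""


class SchemaError(PhenoclaimsError):
    """A required column is missing or a file does not match its schema."""


class RowParseError(PhenoclaimsError):
    """A row-level value could not be parsed; carries the 1-based file line number."""

    def __init__(self, message: str, *, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class ReferentialIntegrityError(PhenoclaimsError):
    """A table references member_ids absent from the members table."""

    def __init__(self, message: str, offenders: list[str]):
        self.offenders = offenders
        super().__init__(message)


class CodeFormatError(PhenoclaimsError):
    """A diagnosis code is empty or malformed."""


class UndefinedEstimateError(PhenoclaimsError):
    """An estimate was requested on an empty denominator."""
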