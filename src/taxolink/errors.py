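"""Exception hierarchy for taxolink."""


class TaxolinkError(Exception):
    """Base class for all taxolink errors."""


class ParseError(TaxolinkError):
    """A dump file (taxdump or wiki XML) could not be parsed.

    Carries the offending location when known (line number for taxdump
    dialect, byte offset for XML).
    """

    def __init__(self, message: str, *, line: int | None = None,
                 offset: int | None = None):
        loc = ""
        if line is not None:
            loc = f" (line {line})"
        elif offset is not None:
            loc = f" (byte offset {offset})"
        super().__init__(message + loc)
        self.line = line
        self.offset = offset


class ValidationError(TaxolinkError):
    """Parsed records violate a structural invariant (duplicate ids,
    dangling parents, multiple accepted names, ...)."""
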