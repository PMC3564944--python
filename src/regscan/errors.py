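"""Exception hierarchy shared across the package."""


class RegscanError(Exception):
    """Base class for all package errors."""


class ValidationError(RegscanError):
    """A value violates a documented invariant (bad coordinates, bad counts...)."""


class FormatError(RegscanError):
    """A file could not be parsed; carries the offending line when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class AliasLookupError(RegscanError):
    """Gene alias not found; message lists near-misses."""


class AmbiguousAliasError(RegscanError):
    """Gene alias maps to more than one canonical gene."""
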