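"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage/config errors -> 2,
data/format errors -> 3, model errors -> 4.
"""


class NeoTadError(Exception):
    """Base class for all package errors."""


class UsageError(NeoTadError):
    """A function was called with arguments that violate its contract."""


class NotationError(NeoTadError):
    """A structural-variant notation string could not be parsed."""

    def __init__(self, message: str, token: str | None = None):
        super().__init__(message if token is None else f"{message} (offending token: {token!r})")
        self.token = token


class CoordinateRangeError(NeoTadError):
    """Coordinates fall outside the declared reference extent."""


class ModelError(NeoTadError):
    """A rearrangement model could not be constructed or applied."""


class DataFormatError(NeoTadError):
    """An input file does not conform to its declared dialect."""


class DegenerateInputError(DataFormatError):
    """Input is syntactically valid but carries no usable signal (e.g. all-N flanks)."""
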