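"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors -> 2 (click), data
validation errors -> 3, model errors -> 4.
"""


class WsforecastError(Exception):
    """Base class for all package errors."""


class DataValidationError(WsforecastError):
    """Malformed or inconsistent input data (exit code 3)."""


class GeneModelError(DataValidationError):
    """A gene model violates its sequence invariants."""


class ModelError(WsforecastError):
    """A model cannot be evaluated on the given inputs (exit code 4)."""


class UndefinedSpectrumError(ModelError):
    """All rate-weighted targets are zero; the spectrum is undefined."""
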