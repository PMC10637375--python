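"""Exception hierarchy for the pipeline.

Every error raised deliberately by this package derives from
:class:`GabafcError`, so callers can catch pipeline failures without
swallowing programming errors.
"""

from __future__ import annotations


class GabafcError(Exception):
    """Base class for all package errors."""


class FormatError(GabafcError):
    """A file does not conform to its declared on-disk format."""


class IntegrityError(GabafcError):
    """Data violates a structural invariant (duplicates, negatives, shape)."""


class PreconditionError(GabafcError):
    """An operation was called on input that violates its contract."""


class EstimationError(GabafcError):
    """A statistic cannot be estimated from the available observations."""


class ValidationError(GabafcError):
    """A configuration object failed validation before any computation."""


class ConfigError(ValidationError):
    """Pipeline configuration error; carries the offending field path."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class GeneLookupError(GabafcError, KeyError):
    """A requested gene symbol is absent; carries near-miss suggestions."""

    def __init__(self, symbol: str, suggestions: list[str] | None = None):
        self.symbol = symbol
        self.suggestions = suggestions or []
        hint = f" (did you mean: {', '.join(self.suggestions)}?)" if self.suggestions else ""
        super().__init__(f"gene symbol {symbol!r} not found{hint}")
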