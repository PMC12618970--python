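"""Exception hierarchy shared across the package."""


class AquaIndexError(Exception):
    """Base class for all package errors."""


class InputError(AquaIndexError):
    """Malformed or unusable input (bad file, empty collection, non-finite value)."""


class StandardsValidationError(AquaIndexError):
    """A parameter standard violates its invariants (degenerate denominator, inverted range, ...)."""


class UnknownParameterError(AquaIndexError, KeyError):
    """A parameter name is not present in the standards table."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the plain message
        return Exception.__str__(self)


class MissingDataError(AquaIndexError):
    """A required parameter is absent from a sample under the strict missing-data policy."""
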