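"""Exception hierarchy shared across the package."""


class MoeYieldError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MoeYieldError, ValueError):
    """A configuration object violates its invariants."""


class UndefinedIndexError(MoeYieldError, ValueError):
    """A vegetation index is undefined for the given reflectances."""


class InvalidInputError(MoeYieldError, ValueError):
    """An input value violates a physical precondition."""


class InsufficientCoverageError(MoeYieldError, ValueError):
    """Too few months observed to assemble a season tensor."""


class NotFittedError(MoeYieldError, RuntimeError):
    """A transformer was applied before being fitted."""


class SchemaError(MoeYieldError, ValueError):
    """A data table violates the expected schema."""
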