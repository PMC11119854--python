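"""Exception hierarchy shared across the package."""


class NeonoxyError(Exception):
    """Base class for all package-specific errors."""


class DomainError(NeonoxyError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DegenerateInputError(NeonoxyError, ValueError):
    """Inputs are individually valid but jointly degenerate (e.g. Cc <= Cv)."""


class InsufficientDataError(NeonoxyError, ValueError):
    """Too few observations to perform a fit."""


class IdentifiabilityError(NeonoxyError, ValueError):
    """The design matrix of a fit is rank deficient."""


class ConvergenceError(NeonoxyError, RuntimeError):
    """An iterative solver failed to converge within its iteration budget."""


class SchemaError(NeonoxyError, ValueError):
    """A data file does not conform to the expected schema."""
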