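"""Exception hierarchy shared across the package."""


class MulticfError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MulticfError, ValueError):
    """A problem configuration is internally inconsistent or incomplete."""


class ConstraintError(MulticfError, ValueError):
    """A user constraint (fixed value or window) conflicts with the feature domain."""


class DataError(MulticfError, ValueError):
    """An input table violates a precondition (missing outcome, too few rows, ...)."""


class ContractViolationError(MulticfError, RuntimeError):
    """A risk model broke the adapter contract (e.g. probability outside [0, 1])."""
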