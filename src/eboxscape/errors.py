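"""Exception hierarchy used across the package."""


class EboxscapeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EboxscapeError, ValueError):
    """An argument violates a documented precondition."""


class CapacityError(EboxscapeError):
    """A synthetic construct does not fit the available sequence space."""


class SchemaError(EboxscapeError):
    """A table is missing required rows/columns or violates its shape contract."""


class MissingNullError(EboxscapeError):
    """No random-category probes available to build an empirical null."""


class InsufficientDataError(EboxscapeError):
    """Too few observations for the requested statistic or fit."""


class NumericalError(EboxscapeError):
    """An iterative numerical routine failed to converge."""


class ConfigurationError(EboxscapeError):
    """Invalid or incomplete analysis configuration."""
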