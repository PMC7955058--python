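"""Exception hierarchy used across the package."""


class Me2VecError(Exception):
    """Base class for all package errors."""


class SchemaError(Me2VecError):
    """An input table is missing a required column or has a malformed header."""


class FormatError(Me2VecError):
    """A serialized artifact violates its declared format."""


class ParameterError(Me2VecError, ValueError):
    """An operation received an out-of-range or degenerate parameter."""


class ConfigError(Me2VecError, ValueError):
    """A configuration object is internally inconsistent."""


class ContractError(Me2VecError):
    """A documented precondition of an operation was violated by the caller."""


class GenerationError(Me2VecError):
    """The synthetic generator cannot satisfy the requested configuration."""


class TrainingError(Me2VecError):
    """A learning task is degenerate (e.g. a single label class)."""


class DependencyError(Me2VecError):
    """A pipeline stage is missing a required upstream artifact."""
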