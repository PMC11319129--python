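"""Exception hierarchy for the rhizostoich pipeline.

Every stage raises a subclass of :class:`RhizostoichError` so drivers can
abort cleanly with the offending stage and keys.
"""


class RhizostoichError(Exception):
    """Base class for all package errors."""


class SchemaError(RhizostoichError):
    """A required column or schema entry is missing or malformed."""


class DataValidationError(RhizostoichError):
    """A value violates a positivity/finiteness invariant."""


class PairingError(RhizostoichError):
    """A plot lacks one of its paired soil compartments."""


class DomainError(RhizostoichError):
    """An input is outside the mathematical domain of a formula
    (non-positive denominator, log of a value <= 1, ...)."""


class ContractError(RhizostoichError):
    """Caller violated an API contract (mismatched keys, mixed headers)."""


class ConfigError(RhizostoichError):
    """Invalid configuration (thresholds, synthetic-data settings)."""


class DesignError(RhizostoichError):
    """The experimental design cannot support the requested analysis
    (empty cells, zero residual df)."""
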