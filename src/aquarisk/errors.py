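"""Exception hierarchy for scenario validation and numerics."""


class AquariskError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AquariskError):
    """A required field is missing or malformed in an input file."""


class TopologyError(AquariskError):
    """River-network topology is invalid (cycle, dangling reference,
    zero or multiple outlets)."""


class ConfigurationError(AquariskError):
    """A configuration value is inconsistent or incomplete."""


class NumericalError(AquariskError):
    """An iterative solver failed to converge; message carries diagnostics."""


class MassBalanceError(AquariskError):
    """The fate mass ledger failed to close within tolerance."""
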