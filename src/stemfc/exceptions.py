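"""Exception hierarchy used across the package."""


class StemfcError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(StemfcError, ValueError):
    """An argument value is outside its valid range."""


class ConfigurationError(StemfcError, ValueError):
    """A requested configuration is internally inconsistent or infeasible."""


class DataError(StemfcError, ValueError):
    """Input data violate a precondition (constant series, collinearity, ...)."""
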