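"""Exception hierarchy shared across the package."""


class AsbestosRiskError(Exception):
    """Base class for all package errors."""


class ValidationError(AsbestosRiskError, ValueError):
    """Raised when data violate a domain invariant (e.g. negative concentration)."""


class ConfigurationError(AsbestosRiskError, ValueError):
    """Raised when a configuration, file layout, or factor name is wrong."""
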