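"""Exception hierarchy shared across the package."""


class MolesimError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MolesimError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(MolesimError, ValueError):
    """A configuration value or key is invalid."""
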