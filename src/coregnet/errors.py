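"""Exception hierarchy shared across the package."""


class CoregnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CoregnetError):
    """A file does not conform to its documented format."""


class IntegrityError(CoregnetError):
    """Inputs are well-formed but mutually inconsistent or structurally invalid."""


class DomainError(CoregnetError, ValueError):
    """An argument violates a mathematical precondition."""


class ConfigError(CoregnetError):
    """A configuration value is invalid or infeasible."""
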