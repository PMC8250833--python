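"""Exception hierarchy shared by all pipeline stages."""


class SandfluxError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SandfluxError):
    """A delimited-text input does not have the expected layout."""


class ValidationError(SandfluxError):
    """Data violate a structural invariant (ragged grid, duplicate depth, ...)."""


class InsufficientDataError(SandfluxError):
    """Too few observations for the requested estimate."""


class DomainError(SandfluxError):
    """A parameter is outside the physically meaningful range."""


class FitError(SandfluxError):
    """Nonlinear least squares failed to converge from every start."""


class ConfigError(SandfluxError):
    """A scenario or run configuration is inconsistent or unstable."""
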