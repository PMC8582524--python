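"""Exception types shared across the package."""


class ReachatError(Exception):
    """Base class for package-specific errors."""


class DegenerateStateError(ReachatError):
    """A quantity is undefined at the supplied tumor state."""


class IntegrationError(ReachatError):
    """The ODE solver failed to converge at the requested tolerances."""


class ConfigurationError(ReachatError):
    """Inconsistent or invalid run configuration."""


class InsufficientDataError(ReachatError):
    """Too few observations or fits to carry out the requested computation."""


class ExtrapolationError(ReachatError):
    """A query point lies outside the fitted/observed range."""


class FitError(ReachatError):
    """All optimization starts failed to converge."""
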