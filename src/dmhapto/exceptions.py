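"""Package-wide exception types."""


class DmhaptoError(Exception):
    """Base class for errors raised by dmhapto."""


class IntegrationError(DmhaptoError):
    """Raised when the explicit-Euler integration produces an invalid state.

    Typically signals that the time step ``dt`` is too large for the
    configured flux rates (a concentration would become negative).
    """


class FitError(DmhaptoError):
    """Raised when a nonlinear least-squares fit cannot be performed."""


class SchemaError(DmhaptoError):
    """Raised when a delimited-text table violates its declared schema."""


class ConfigError(DmhaptoError):
    """Raised for invalid, unknown, or unparseable configuration keys."""
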