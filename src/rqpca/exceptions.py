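"""Exception hierarchy shared across the package."""


class RqpcaError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RqpcaError, ValueError):
    """An argument violates a documented precondition."""


class SingularBackgroundError(RqpcaError, ValueError):
    """The regularized background covariance is not positive definite."""


class DegenerateDirectionError(RqpcaError, ValueError):
    """A direction has non-positive background variance."""


class AlignmentError(RqpcaError, ValueError):
    """Identifier lists or dimensions of paired inputs do not match."""


class ZeroSpreadError(RqpcaError, ValueError):
    """All spatial locations coincide; no bandwidth can be derived."""


class AccuracyError(RqpcaError, ValueError):
    """A quadrature rule failed its self-consistency check."""


class NotPSDError(RqpcaError, ValueError):
    """A matrix required to be positive semi-definite is not."""


class EmptyResultError(RqpcaError, ValueError):
    """A filtering step removed every observation."""


class ParseError(RqpcaError, ValueError):
    """An on-disk file could not be parsed or is internally inconsistent."""


class ConfigError(RqpcaError, ValueError):
    """A run configuration value is invalid."""
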