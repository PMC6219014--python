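"""Exception hierarchy shared across the package."""


class TaviewError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(TaviewError, ValueError):
    """An argument violates a documented precondition."""


class GeometryError(TaviewError, ValueError):
    """A mesh or a geometric query is degenerate or inconsistent."""


class FormatError(TaviewError, ValueError):
    """A file does not parse as the advertised dialect."""


class IntegrationError(TaviewError, RuntimeError):
    """Time integration left the stable regime."""


class DegeneracyError(TaviewError, RuntimeError):
    """A Monte Carlo ensemble or sampler collapsed."""


class NumericalError(TaviewError, RuntimeError):
    """A linear-algebra step failed beyond recoverable tolerance."""
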