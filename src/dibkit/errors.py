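"""Exception hierarchy shared across dibkit modules."""


class DibkitError(Exception):
    """Base class for all dibkit errors."""


class InvalidGeometryError(DibkitError, ValueError):
    """Droplet geometry violates its invariants (e.g. r > min(R1, R2))."""


class DomainError(DibkitError, ValueError):
    """A scalar input lies outside the physically meaningful domain."""


class CannotEstimateError(DibkitError, RuntimeError):
    """The requested parameter is unidentifiable from the given data."""


class IntegrationError(DibkitError, RuntimeError):
    """Forward simulation aborted (e.g. a droplet volume driven nonpositive)."""


class FitError(DibkitError, RuntimeError):
    """An optimisation failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best: float | None = None,
                 residual: float | None = None):
        super().__init__(message)
        self.best = best
        self.residual = residual


class ParseError(DibkitError, ValueError):
    """A data file failed validation; names the offending path/line."""
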