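"""Exception hierarchy shared across the package."""


class EarlyfoldError(Exception):
    """Base class for all package-specific errors."""


class ChainNotFoundError(EarlyfoldError):
    """Requested chain id is absent from the structure file."""


class NoBackboneError(EarlyfoldError):
    """No residue in the chain carries a complete N/CA/C backbone."""


class EmptyDomainError(EarlyfoldError):
    """A domain range selects no residues."""


class TooShortError(EarlyfoldError):
    """Domain is below the minimum length required for analysis."""


class DegenerateGeometryError(EarlyfoldError):
    """Coincident or collinear atoms make a geometric quantity undefined."""


class NoDihedralsError(EarlyfoldError):
    """No phi/psi angle can be computed for the domain."""


class NotOnEllipseError(EarlyfoldError):
    """A point handed to t_angle does not satisfy the ellipse equation."""


class NoMaximaError(EarlyfoldError):
    """A flat histogram has no local maxima."""


class CannotDeriveEllipseError(EarlyfoldError):
    """Too few on-path points survive the residual filter."""


class NotEllipticalError(EarlyfoldError):
    """The algebraic conic fit did not produce an ellipse."""


class DegenerateSpreadError(EarlyfoldError):
    """All effective positions coincide; the 3D Gaussian is undefined."""


class ZeroHydrophobicityError(EarlyfoldError):
    """All intrinsic hydrophobicities are zero; O cannot be normalized."""


class UnboundedDivergenceError(EarlyfoldError):
    """Kullback-Leibler divergence is infinite (P > 0 where Q = 0)."""


class UndefinedCorrelationError(EarlyfoldError):
    """Pearson correlation is undefined (constant vector)."""
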