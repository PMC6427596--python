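"""Exception hierarchy shared across the pipeline stages."""


class PhenocloudError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PhenocloudError):
    """A point-cloud file could not be parsed; the message names the line."""


class EmptyCloudError(PhenocloudError):
    """An operation received a cloud with zero points."""


class ParameterError(PhenocloudError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateNeighborhoodError(PhenocloudError):
    """A local neighborhood is too small for covariance analysis."""


class DegenerateGeometryError(PhenocloudError):
    """Input points cannot constrain the requested primitive fit."""


class InsufficientStemPointsError(PhenocloudError):
    """Too few points survive stem-window gating for a cylinder fit."""

    def __init__(self, n_window: int, n_gated: int, needed: int = 6):
        self.n_window = n_window
        self.n_gated = n_gated
        self.needed = needed
        super().__init__(
            f"stem fit needs >= {needed} points, window contained "
            f"{n_window}, {n_gated} after radial gating"
        )
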