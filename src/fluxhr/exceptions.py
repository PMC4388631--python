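"""Exception hierarchy for fluxhr.

All package-specific failures derive from :class:`FluxHRError` so callers can
catch the whole family with one clause while tests can assert on the precise
failure mode.
"""


class FluxHRError(Exception):
    """Base class for all fluxhr errors."""


class ModelFormatError(FluxHRError):
    """A model file could not be parsed; the message names the offending element."""


class ModelValidationError(FluxHRError):
    """A parsed model violates a structural invariant (dimensions, bounds, ids)."""


class InfeasibleModelError(FluxHRError):
    """The constraint set {S v = 0, lb <= v <= ub} admits no feasible point."""


class DegeneratePolytopeError(FluxHRError):
    """The feasible set has no interior (dimension 0, or a single point)."""


class DegenerateChordError(FluxHRError):
    """A chord narrower than the chord-width floor; the sampler resamples the direction."""


class FrozenDynamicsError(FluxHRError):
    """Direction resampling exceeded its cap: the walk cannot move."""


class LPSolverError(FluxHRError):
    """A linear program failed; the message carries the variable index and solver status."""


class DimensionCollapseError(FluxHRError):
    """An axis search found a direction of negligible extent before spanning all of R^D."""


class EmptyCutError(FluxHRError):
    """A half-space cut leaves an empty intersection with the ellipsoid (depth >= 1)."""


class NonConvergenceError(FluxHRError):
    """An iterative procedure exhausted its iteration budget."""


class InsufficientDataError(FluxHRError):
    """Too few (effective) samples to run the requested estimator."""


class GeneratorError(FluxHRError):
    """A synthetic-polytope generator failed to produce a valid instance."""
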