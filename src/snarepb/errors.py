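"""Exception hierarchy."""


class SnarePBError(Exception):
    """Base class for all package errors."""


class ParseError(SnarePBError):
    """Malformed structure file; message names the offending line."""


class ConfigurationError(SnarePBError):
    """Invalid configuration value or unknown format token."""


class LookupFailure(SnarePBError):
    """Parameter assignment failed with fallback disabled."""


class DegenerateAxisError(SnarePBError):
    """Anchor atoms coincide; alignment axis undefined."""


class PlacementError(SnarePBError):
    """Structure cannot be placed against the membrane (footprint/margin)."""


class GeometryError(SnarePBError):
    """Membrane geometry request is unsatisfiable."""


class EmbeddingError(SnarePBError):
    """TMD segment lies outside the slab it should be embedded in."""


class BoundsError(SnarePBError):
    """System extends beyond the requested grid."""


class ConvergenceError(SnarePBError):
    """Solver failed to reach the residual tolerance."""


class SweepError(SnarePBError):
    """Invalid sweep request (too few points, unordered values...)."""


class InterpolationError(SnarePBError):
    """Query outside the range covered by an energy curve."""


class SpecError(SnarePBError):
    """Impossible synthetic-fixture specification."""
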