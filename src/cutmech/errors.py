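"""Exception hierarchy shared across the package."""


class CutmechError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CutmechError, ValueError):
    """An input violates a documented precondition or type invariant."""


class TraceFormatError(CutmechError, ValueError):
    """A trace file could not be parsed into a valid force trace."""


class InsufficientSteadyStateError(CutmechError):
    """The post-peak travel is too short to hold the steady-state window."""


class GeometryError(CutmechError):
    """Base class for edge-geometry estimation failures."""


class NoFlanksError(GeometryError):
    """Fewer than two straight flank runs were detected on the contour."""


class DegenerateGeometryError(GeometryError):
    """Flank lines are (nearly) parallel; no wedge apex exists."""


class EstimationFailureError(GeometryError):
    """No bitangent circle fits inside the cross-section up to its extent."""
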