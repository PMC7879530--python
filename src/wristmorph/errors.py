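"""Exception hierarchy for wristmorph."""


class WristmorphError(Exception):
    """Base class for all wristmorph errors."""


class ConstraintViolationError(WristmorphError):
    """A synthetic-template constraint band is violated; the message names the band."""


class MeshError(WristmorphError):
    """Degenerate or malformed surface mesh input."""


class AxisFitError(WristmorphError):
    """Long-axis estimation failed (empty band, rank-deficient centroids)."""


class OriginError(WristmorphError):
    """The long axis does not intersect the articular surface."""


class FrameError(WristmorphError):
    """Degenerate landmarks for anatomical frame construction."""


class RegistrationError(WristmorphError):
    """Rigid registration could not be performed on the given point sets."""


class DegenerateProjectionError(WristmorphError):
    """An angle's projection onto its radiographic plane is degenerate."""


class StatsError(WristmorphError):
    """Invalid input to a cohort-statistics routine."""


class SchemaError(WristmorphError):
    """A file failed schema validation; the message names the offending field."""
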