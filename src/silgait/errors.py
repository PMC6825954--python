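"""Exception hierarchy.

Every error raised by the library derives from :class:`SilgaitError`, so
callers (and the CLI) can distinguish validation problems from bugs.
"""


class SilgaitError(Exception):
    """Base class for all silgait errors."""


class InputError(SilgaitError):
    """A required input is missing or unusable (e.g. empty frame directory)."""


class ShapeError(InputError):
    """Image dimensions are inconsistent."""


class ParseError(InputError):
    """A file's content cannot be interpreted (bad labels, non-integer frames)."""


class SchemaError(InputError):
    """A table is missing required columns."""


class ValidationError(InputError):
    """Values violate the input contract (negative times, missing paw side)."""


class ParameterError(SilgaitError):
    """A numeric parameter is out of its valid domain."""


class MissingPawError(SilgaitError):
    """A paw never appears in the detection log, so no window exists."""


class EmptyWindowError(SilgaitError):
    """The computed analysis window is empty (f_start > f_stop)."""


class NoSilhouetteError(SilgaitError):
    """No foreground silhouette could be extracted."""


class ScalingError(SilgaitError):
    """Scaling failed (non-positive denominator)."""


class MethodError(ScalingError):
    """A scaling method was applied to an incompatible parameter."""


class AggregationError(SilgaitError):
    """Run-to-animal aggregation received no runs."""


class DesignError(SilgaitError):
    """A statistical design is unusable (missing cells, empty group)."""


class RenderError(SilgaitError):
    """Synthetic geometry does not fit inside the frame."""
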