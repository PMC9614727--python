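"""Exception hierarchy.

All poreflux errors derive from :class:`PorefluxError`; most double as
``ValueError`` so that plain input-validation idioms keep working.
"""


class PorefluxError(Exception):
    """Base class for all poreflux errors."""


class FormatError(PorefluxError, ValueError):
    """A structure/trajectory file does not parse under its declared format."""


class UnsupportedFormatError(FormatError):
    """The requested file format is not one this package reads or writes."""


class TrajectoryError(PorefluxError, ValueError):
    """Structural problem in a trajectory (particle counts, time order, box)."""


class EmptyInputError(TrajectoryError):
    """A trajectory or selection that must be non-empty is empty."""


class UnwrapAmbiguityError(PorefluxError, ValueError):
    """Per-frame displacement reaches half the box edge: the minimum-image
    unwrapping is ambiguous and the trajectory needs denser sampling."""


class WrappedInputError(PorefluxError, ValueError):
    """An analysis that requires axis-unwrapped coordinates received wrapped
    input (a jump larger than half the box edge was detected)."""


class DomainError(PorefluxError, ValueError):
    """A numeric parameter is outside its physical domain (e.g. d <= 0)."""


class InsufficientDataError(PorefluxError, ValueError):
    """Not enough data points for the requested estimate."""


class UsageError(PorefluxError, ValueError):
    """Mutually exclusive or missing arguments."""
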