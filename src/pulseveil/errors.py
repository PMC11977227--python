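"""Exception hierarchy.

All pulseveil errors derive from :class:`PulseveilError` so callers can catch
one base class; subclasses distinguish configuration mistakes (bad parameter
values) from data problems (unreadable files, degenerate geometry, signals
too short to window).
"""


class PulseveilError(Exception):
    """Base class for all pulseveil errors."""


class ConfigError(PulseveilError):
    """Invalid parameter value (even kernel, negative sigma, bad method name)."""


class FormatError(PulseveilError):
    """Unreadable or malformed input file."""


class EmptyInputError(PulseveilError):
    """An input that must be non-empty is empty."""


class GeometryError(PulseveilError):
    """Degenerate landmark geometry (fewer than 3 non-collinear points)."""


class DetectionError(PulseveilError):
    """Landmark provider found no face in a frame."""


class DimensionError(PulseveilError):
    """Mismatched array shapes between frames, masks or videos."""


class StateError(PulseveilError):
    """A stateful filter was fed a frame inconsistent with its state."""


class SamplingError(PulseveilError):
    """RGB patch sampling produced an empty pixel set."""


class InsufficientDataError(PulseveilError):
    """Signal shorter than one analysis window, or list too short to normalize."""


class DecompositionError(PulseveilError):
    """ICA / SVD failed or the input is rank deficient."""


class NormalizationError(PulseveilError):
    """A channel mean needed for normalization is zero."""


class UndefinedPeakError(PulseveilError):
    """Power spectrum has no usable peak (all-zero signal)."""


class AlignmentError(PulseveilError):
    """Two series that must be aligned differ in length or timestamps."""
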