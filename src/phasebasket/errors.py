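"""Exception hierarchy for the phasebasket pipeline."""


class PhaseBasketError(Exception):
    """Base class for all phasebasket errors."""


class FormatError(PhaseBasketError):
    """A file does not conform to the documented dialect."""


class GeometryError(PhaseBasketError):
    """Electrode geometry or mesh topology is invalid."""


class UsageError(PhaseBasketError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateSignalError(PhaseBasketError):
    """A signal has no usable content (all-zero, flat spectrum, ...)."""


class LocationError(PhaseBasketError):
    """A point could not be located on a mesh face within tolerance."""


class CorrespondenceError(PhaseBasketError):
    """Two meshes do not share the face indexing required for transfer."""


class UndefinedStatisticError(PhaseBasketError):
    """A statistic is undefined for the given input (zero variance, ...)."""
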