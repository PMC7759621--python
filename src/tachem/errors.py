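"""Exception hierarchy."""


class TachemError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TachemError):
    """A scenario or fit configuration is internally inconsistent."""


class ValidityRangeError(TachemError):
    """Requested conditions fall outside the chemical validity window
    (e.g. pH below 3.5, where Fe(III) reduction by the ligand sets in)."""


class InitializationError(TachemError):
    """Pure-variable initialization cannot proceed (degenerate data)."""


class OverMaskingError(TachemError):
    """Scatter masking would remove an entire emission slice."""


class InterpolationError(TachemError):
    """A fully-masked slice cannot be interpolated."""


class NoSaturationError(TachemError):
    """No plateau detected in a saturation series."""


class UnbracketedMaximumError(TachemError):
    """The maximum of a continuous-variation series sits at the edge
    of the measured molar-fraction grid."""


class FreeMetalExhaustedError(TachemError):
    """Free-metal concentration at or below the numeric floor; a
    conditional constant cannot be computed."""
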