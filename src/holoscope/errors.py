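"""Exception hierarchy for the holoscope pipeline."""


class HoloscopeError(Exception):
    """Base class for all package errors."""


class InvalidConfigurationError(HoloscopeError, ValueError):
    """An optical or acquisition configuration violates its invariants."""


class ContractError(HoloscopeError, ValueError):
    """Metadata of two objects that must agree (wavelength, pitch, shape) differ."""


class ResolutionError(HoloscopeError, ValueError):
    """A requested structure is too fine for the sampling grid."""


class PackingError(HoloscopeError, RuntimeError):
    """Random placement of phantom objects failed within the retry budget."""


class PlanningError(HoloscopeError, ValueError):
    """An LED grid plan does not fit on the physical display."""


class DegenerateFrameError(HoloscopeError, ValueError):
    """A hologram frame carries no signal above the background."""


class GeometryError(HoloscopeError, ValueError):
    """A profile line or ROI leaves the image bounds."""


class NoEdgeError(HoloscopeError, ValueError):
    """An edge profile never crosses the requested threshold levels."""


class UndefinedContrastError(HoloscopeError, ValueError):
    """Michelson contrast is undefined (all-zero profile)."""


class AmbiguousFocusError(HoloscopeError, RuntimeError):
    """The autofocus metric is flat over the whole search range."""


class FormatError(HoloscopeError, ValueError):
    """An on-disk hologram set is inconsistent with its descriptor."""
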