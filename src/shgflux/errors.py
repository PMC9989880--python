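"""Exception hierarchy shared across the pipeline."""


class ShgFluxError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ShgFluxError, ValueError):
    """A parameter violates a documented invariant."""


class GeometryError(ShgFluxError, ValueError):
    """A ring/band does not fit the image it is applied to."""


class NoRingDetectedError(ShgFluxError, RuntimeError):
    """Ring detection found no circle with contrast above threshold."""


class EmptyMapError(ShgFluxError, RuntimeError):
    """Every ROI fit failed; no decay map can be assembled."""


class NumericalError(ShgFluxError, RuntimeError):
    """A root-find or integrator could not produce a reliable answer."""
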