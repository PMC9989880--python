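"""Ring geometry of a GUV equatorial section in an image."""

from __future__ import annotations

from dataclasses import dataclass, replace

from shgflux.errors import InvalidParameterError


@dataclass(frozen=True)
class GUVGeometry:
    """Detected (or prescribed) equatorial ring of a GUV.

    Pixel coordinates follow image convention: origin at the top-left pixel
    center, x to the right, y down.  Angles elsewhere in the package are
    measured counterclockwise from +x (so "up" in the displayed image is
    +90 degrees), in degrees.

    Attributes
    ----------
    center : (float, float)
        Ring center ``(cx, cy)`` in pixels.
    radius_um : float
        Ring radius R in micrometres.
    band_halfwidth_um : float
        Radial half-width of the integration band around R, micrometres.
    pixel_size_um : float
        Image scale, micrometres per pixel; carried here so that every
        consumer of the geometry converts lengths identically.
    """

    center: tuple[float, float]
    radius_um: float
    band_halfwidth_um: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise InvalidParameterError("radius_um must be positive")
        if self.band_halfwidth_um <= 0:
            raise InvalidParameterError("band_halfwidth_um must be positive")
        if self.pixel_size_um <= 0:
            raise InvalidParameterError("pixel_size_um must be positive")

    @property
    def radius_px(self) -> float:
        return self.radius_um / self.pixel_size_um

    @property
    def band_halfwidth_px(self) -> float:
        return self.band_halfwidth_um / self.pixel_size_um

    def with_radius(self, radius_um: float) -> "GUVGeometry":
        return replace(self, radius_um=radius_um)

    def fits_inside(self, shape: tuple[int, int], margin_px: float = 0.0) -> bool:
        """Whether the outer band edge stays inside an image of ``shape``."""
        h, w = shape
        cx, cy = self.center
        outer = self.radius_px + self.band_halfwidth_px + margin_px
        return (
            cx - outer >= 0
            and cy - outer >= 0
            and cx + outer <= w - 1
            and cy + outer <= h - 1
        )
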