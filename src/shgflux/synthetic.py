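"""Synthetic wide-field SH movies of GUV equatorial sections.

Second-harmonic generation is dipole-forbidden in centrosymmetric media, so a
symmetric charged bilayer with identically hydrated leaflets emits no SH
light.  Adding CaCl2 to the outside breaks the symmetry: Ca2+ binds the outer
headgroups and reorients interfacial water, producing a bright equatorial
ring.  As ions translocate, the leaflets re-symmetrize and the ring intensity
decays exponentially with an angle-dependent time constant tau(theta).

This module renders that phenomenology with known ground truth:

* a bright ring of radius R with Gaussian radial cross-section (PSF),
* cos^2(theta - polarization) angular modulation from the projection of the
  optical field onto the interface,
* micrometre-scale bright/dark domains along the rim via a correlated
  lognormal tau(theta) field,
* per-angle exponential intensity decay after t = 0 (salt addition),
* EM-CCD noise: Poisson shot noise, Gaussian read noise, background offset.

Conventions: SH *intensity* is proportional to the squared net oriented-water
amplitude.  Composition presets parameterize the intensity decay time tau, so
fitted time constants are directly comparable to experimental ROI fits; the
stored leaflet asymmetry is the square root of the intensity envelope and
decays with time constant 2*tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from shgflux.errors import GeometryError, InvalidParameterError
from shgflux.geometry import GUVGeometry
from shgflux.streams import substream

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Reference GUV radius (um) used to convert rim correlation lengths to angle.
REFERENCE_RADIUS_UM = 10.0


@dataclass(frozen=True)
class OpticsConfig:
    """Optical and camera parameters of the wide-field SH microscope.

    Defaults emulate the instrument scale: 400 nm lateral resolution, a
    90 um illuminated field, 5 s accumulation per frame, and an EM-ICCD
    noise model.  ``peak_rate * exposure`` sets the expected ring-crest
    counts above background; the default gives an initial crest
    signal-to-noise ratio of about 20.
    """

    pixel_size: float = 0.4  # um per pixel
    psf_fwhm: float = 0.4  # um
    polarization_angle: float = 90.0  # degrees, counterclockwise from +x
    illumination_diameter: float = 90.0  # um
    exposure: float = 5.0  # s
    em_gain: float = 1.0
    read_noise_sd: float = 3.0  # counts
    background_level: float = 100.0  # counts
    peak_rate: float = 90.0  # counts / s at the ring crest
    #: Frame-to-frame RMS of the global SH illumination factor.  Wide-field
    #: SH intensity scales with the square of the fundamental power, so a ~1%
    #: laser fluctuation appears as ~2% correlated scatter on every frame;
    #: this term dominates the noise of the *integrated* trace and sets the
    #: practical noise floor of a decaying GUV signal.
    flicker_rel_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")
        if self.psf_fwhm <= 0:
            raise InvalidParameterError("psf_fwhm must be positive")
        if not (0.0 <= self.polarization_angle < 180.0):
            raise InvalidParameterError("polarization_angle must be in [0, 180)")
        if self.em_gain < 1:
            raise InvalidParameterError("em_gain must be >= 1")
        if self.read_noise_sd < 0:
            raise InvalidParameterError("read_noise_sd must be >= 0")
        if self.exposure <= 0:
            raise InvalidParameterError("exposure must be positive")
        if self.peak_rate < 0:
            raise InvalidParameterError("peak_rate must be >= 0")
        if self.flicker_rel_sd < 0:
            raise InvalidParameterError("flicker_rel_sd must be >= 0")

    @property
    def peak_counts(self) -> float:
        """Expected background-subtracted counts at the ring crest."""
        return self.peak_rate * self.exposure


@dataclass(frozen=True)
class CompositionPreset:
    """Membrane composition phenomenology.

    ``tau_base`` is the geometric-mean *intensity* decay time in seconds
    (``math.inf`` for compositions that do not translocate Ca2+);
    ``tau_spatial_ratio`` the max/min heterogeneity of tau along the rim;
    ``domain_correlation_length`` the rim-domain scale in micrometres;
    ``sigma`` the headgroup charge density magnitude in C/m^2.
    """

    name: str
    tau_base: float
    tau_spatial_ratio: float
    domain_correlation_length: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.tau_base > 0):  # also rejects NaN
            raise InvalidParameterError("tau_base must be positive or inf")
        if self.tau_spatial_ratio < 1:
            raise InvalidParameterError("tau_spatial_ratio must be >= 1")
        if self.domain_correlation_length <= 0:
            raise InvalidParameterError("domain_correlation_length must be positive")
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")

    @property
    def translocating(self) -> bool:
        return math.isfinite(self.tau_base)


# Printed ROI fits for the mono-unsaturated membrane span 4-13 min; the decay
# map varies roughly threefold along the rim.  tau_base is the geometric mean
# of the 4- and 13-min extremes so a threefold field spans ~[250, 749] s.
_TAU_FAST_S = 240.0
_TAU_SLOW_S = 780.0
_TAU_BASE_S = math.sqrt(_TAU_FAST_S * _TAU_SLOW_S)  # ~432.7 s
#: Cholesterol slows the average SH decay by about a factor of 10.
CHOLESTEROL_SLOWDOWN = 10.0

PRESETS: dict[str, CompositionPreset] = {
    "DOPC:DOPA": CompositionPreset(
        name="DOPC:DOPA",
        tau_base=_TAU_BASE_S,
        tau_spatial_ratio=3.0,
        domain_correlation_length=2.0,
        sigma=1e-3,
    ),
    "DOPC:DOPA:Chol": CompositionPreset(
        name="DOPC:DOPA:Chol",
        tau_base=_TAU_BASE_S * CHOLESTEROL_SLOWDOWN,
        tau_spatial_ratio=3.0,
        domain_correlation_length=2.0,
        sigma=1e-3,
    ),
    "DPhPC:DPhPA": CompositionPreset(
        name="DPhPC:DPhPA",
        tau_base=math.inf,
        tau_spatial_ratio=1.0,
        domain_correlation_length=2.0,
        sigma=1e-3,
    ),
    "SLPC:SLPA": CompositionPreset(
        name="SLPC:SLPA",
        tau_base=math.inf,
        tau_spatial_ratio=1.0,
        domain_correlation_length=2.0,
        sigma=1e-3,
    ),
}


@dataclass(frozen=True)
class TauField:
    """Ground-truth per-angle intensity decay times along the rim."""

    theta_grid: np.ndarray  # degrees in [0, 360)
    tau: np.ndarray  # seconds; may be inf
    seed: int

    def __post_init__(self) -> None:
        if len(self.theta_grid) != len(self.tau):
            raise InvalidParameterError("theta_grid and tau must have equal length")
        if np.any(self.tau <= 0) or np.any(np.isnan(self.tau)):
            raise InvalidParameterError("tau must be strictly positive")

    @property
    def finite(self) -> bool:
        return bool(np.all(np.isfinite(self.tau)))

    def tau_at(self, theta_deg: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation of tau at arbitrary angles."""
        return _periodic_interp(theta_deg, self.theta_grid, self.tau)


@dataclass(frozen=True)
class AsymmetryField:
    """Leaflet bound-Ca2+ asymmetry, normalized to 1 at t = 0.

    Rendered SH intensity is proportional to ``asymmetry**2``, so a field
    built from an intensity decay time tau carries amplitude time 2*tau.
    """

    theta_grid: np.ndarray  # degrees
    time_grid: np.ndarray  # seconds
    asymmetry: np.ndarray  # shape (n_time, n_theta), values in [0, 1]


@dataclass(frozen=True)
class TruthBundle:
    geometry: GUVGeometry
    tau_field: TauField
    preset: CompositionPreset


@dataclass(frozen=True)
class SHMovie:
    """Time-stamped stack of SH images with optics metadata."""

    frames: np.ndarray  # (n_frames, h, w), nonnegative counts
    timestamps: np.ndarray  # s, strictly increasing
    optics: OpticsConfig
    truth: TruthBundle | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (t, y, x) stack")
        if len(self.timestamps) != len(self.frames):
            raise InvalidParameterError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps) <= 0):
            raise InvalidParameterError("timestamps must be strictly increasing")
        if np.any(self.frames < 0):
            raise InvalidParameterError("frame counts must be nonnegative")


def _periodic_interp(x_deg, grid_deg, values):
    x = np.asarray(x_deg, dtype=float) % 360.0
    gx = np.concatenate([grid_deg, [grid_deg[0] + 360.0]])
    gv = np.concatenate([values, [values[0]]])
    return np.interp(x, gx, gv)


def _periodic_gaussian_field(n_theta: int, corr_deg: float, rng) -> np.ndarray:
    """Zero-mean correlated Gaussian field on the circle (FFT smoothing)."""
    z = rng.standard_normal(n_theta)
    theta = np.arange(n_theta) * (360.0 / n_theta)
    d = np.minimum(theta, 360.0 - theta)
    kernel = np.exp(-0.5 * (d / corr_deg) ** 2)
    kernel /= kernel.sum()
    f = np.fft.irfft(np.fft.rfft(z) * np.fft.rfft(kernel), n=n_theta)
    return f


def make_tau_field(
    preset: CompositionPreset,
    n_theta: int = 360,
    seed: int = 0,
    reference_radius_um: float = REFERENCE_RADIUS_UM,
) -> TauField:
    """Draw a periodic correlated lognormal tau(theta) field.

    log-tau is a stationary Gaussian field on the circle whose correlation
    length is the preset's rim-domain length converted to angle at
    ``reference_radius_um``; the field is then min-max rescaled in log space
    so that max(tau)/min(tau) equals ``tau_spatial_ratio`` exactly and the
    geometric mean of the extremes equals ``tau_base``.  Non-translocating
    presets return an all-infinite field.
    """
    if n_theta < 8:
        raise InvalidParameterError("n_theta must be >= 8")
    if preset.domain_correlation_length <= 0:
        raise InvalidParameterError("domain_correlation_length must be positive")
    theta = np.arange(n_theta) * (360.0 / n_theta)
    if not preset.translocating:
        return TauField(theta_grid=theta, tau=np.full(n_theta, np.inf), seed=seed)
    ratio = preset.tau_spatial_ratio
    if ratio == 1.0:
        return TauField(theta_grid=theta, tau=np.full(n_theta, preset.tau_base), seed=seed)
    corr_deg = math.degrees(preset.domain_correlation_length / reference_radius_um)
    rng = substream(seed, "tau_field")
    f = _periodic_gaussian_field(n_theta, corr_deg, rng)
    span = f.max() - f.min()
    if span <= 0:  # pragma: no cover - degenerate draw
        g = np.full(n_theta, 0.5)
    else:
        g = (f - f.min()) / span
    log_lo = math.log(preset.tau_base / math.sqrt(ratio))
    tau = np.exp(log_lo + g * math.log(ratio))
    return TauField(theta_grid=theta, tau=tau, seed=seed)


def simulate_asymmetry(tau_field: TauField, time_grid) -> AsymmetryField:
    """Realize the leaflet asymmetry envelope on a time grid.

    The SH *intensity* envelope at angle theta is exp(-t / tau(theta)); the
    stored asymmetry is its square root, exp(-t / (2 tau)), so that rendered
    intensity (proportional to asymmetry squared) carries time constant tau.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0 or t[0] != 0.0:
        raise InvalidParameterError("time grid must start at 0")
    if np.any(t < 0):
        raise InvalidParameterError("times must be nonnegative")
    with np.errstate(divide="ignore"):
        rate = np.where(np.isfinite(tau_field.tau), 1.0 / (2.0 * tau_field.tau), 0.0)
    asym = np.exp(-np.outer(t, rate))
    return AsymmetryField(theta_grid=tau_field.theta_grid, time_grid=t, asymmetry=asym)


def _noise_free_signal(
    geometry: GUVGeometry,
    theta_grid_deg: np.ndarray,
    asymmetry_slice: np.ndarray,
    optics: OpticsConfig,
    shape: tuple[int, int],
) -> np.ndarray:
    h, w = shape
    cx, cy = geometry.center
    y, x = np.mgrid[0:h, 0:w].astype(float)
    dx = x - cx
    dy = y - cy
    r = np.hypot(dx, dy)
    # image y points down; theta is counterclockwise from +x
    theta = np.degrees(np.arctan2(-dy, dx)) % 360.0
    sigma_px = optics.psf_fwhm * FWHM_TO_SIGMA / optics.pixel_size
    radial = np.exp(-0.5 * ((r - geometry.radius_px) / sigma_px) ** 2)
    asym = _periodic_interp(theta, theta_grid_deg, asymmetry_slice)
    ang = np.cos(np.radians(theta - optics.polarization_angle)) ** 2
    return optics.peak_counts * (asym**2) * ang * radial


def render_frame(
    geometry: GUVGeometry,
    asymmetry_slice,
    optics: OpticsConfig,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    theta_grid=None,
    noise: bool = True,
) -> np.ndarray:
    """Render one SH frame (counts) from a per-angle asymmetry slice.

    The noise-free signal is a ring of radius R with Gaussian radial
    cross-section (FWHM = psf_fwhm) modulated by
    ``asymmetry(theta)^2 * cos^2(theta - polarization)`` and scaled to the
    configured crest counts.  Noise: Poisson shot noise (scaled by EM gain),
    additive Gaussian read noise, then the constant background offset.
    """
    asymmetry_slice = np.asarray(asymmetry_slice, dtype=float)
    if theta_grid is None:
        theta_grid = np.arange(len(asymmetry_slice)) * (360.0 / len(asymmetry_slice))
    if not geometry.fits_inside(shape, margin_px=3.0 * optics.psf_fwhm
                                * FWHM_TO_SIGMA / optics.pixel_size):
        raise GeometryError("ring (plus band and PSF tails) does not fit inside frame")
    signal = _noise_free_signal(geometry, np.asarray(theta_grid, float),
                                asymmetry_slice, optics, shape)
    if not noise:
        return signal + optics.background_level
    rng = substream(seed, "render")
    photons = rng.poisson(signal / optics.em_gain)
    counts = (
        optics.em_gain * photons
        + rng.normal(0.0, optics.read_noise_sd, size=signal.shape)
        + optics.background_level
    )
    return np.clip(counts, 0.0, None)


def generate_movie(
    preset: CompositionPreset,
    geometry: GUVGeometry,
    optics: OpticsConfig,
    schedule,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    n_theta: int = 360,
    noise: bool = True,
) -> SHMovie:
    """Generate a full SH movie from one tau field; reproducible from seed."""
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise InvalidParameterError("schedule must be nonempty")
    if np.any(np.diff(schedule) <= 0):
        raise InvalidParameterError("schedule must be strictly increasing")
    tau_field = make_tau_field(preset, n_theta=n_theta, seed=seed)
    # envelope is defined from t = 0 (salt addition) even if acquisition
    # starts later
    times = schedule if schedule[0] == 0.0 else np.concatenate([[0.0], schedule])
    asym = simulate_asymmetry(tau_field, times)
    offset = 0 if schedule[0] == 0.0 else 1
    frames = np.stack(
        [
            _render_indexed(
                geometry, asym.asymmetry[offset + i], optics, seed, i, shape,
                tau_field.theta_grid, noise,
            )
            for i in range(len(schedule))
        ]
    )
    truth = TruthBundle(geometry=geometry, tau_field=tau_field, preset=preset)
    return SHMovie(frames=frames, timestamps=schedule, optics=optics, truth=truth)


def _render_indexed(geometry, asym_slice, optics, seed, index, shape, theta_grid, noise):
    """Render frame ``index`` with a frame-specific child seed and flicker.

    The global illumination factor (mean 1, sd ``flicker_rel_sd``) multiplies
    the frame's SH signal — not the camera background — emulating correlated
    shot-to-shot laser fluctuations.  Noise-free renders omit it.
    """
    if not noise:
        return render_frame(geometry, asym_slice, optics, seed=0, shape=shape,
                            theta_grid=theta_grid, noise=False)
    sub = substream(seed, "frame", index)
    frame_seed = int(sub.integers(0, 2**31 - 1))
    factor = max(1.0 + optics.flicker_rel_sd * sub.standard_normal(), 0.0)
    return render_frame(geometry, asym_slice * math.sqrt(factor), optics,
                        seed=frame_seed, shape=shape,
                        theta_grid=theta_grid, noise=True)


def default_geometry(
    radius_um: float = 10.0,
    shape: tuple[int, int] = (64, 64),
    optics: OpticsConfig | None = None,
) -> GUVGeometry:
    """Centered geometry with the standard 2x-PSF-FWHM integration band."""
    optics = optics or OpticsConfig()
    h, w = shape
    return GUVGeometry(
        center=((w - 1) / 2.0, (h - 1) / 2.0),
        radius_um=radius_um,
        band_halfwidth_um=2.0 * optics.psf_fwhm,
        pixel_size_um=optics.pixel_size,
    )


def default_schedule(n_frames: int = 30, period_s: float = 60.0) -> np.ndarray:
    """Acquisition times emulating repeated imaging with a 1-min period."""
    return np.arange(n_frames, dtype=float) * period_s
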