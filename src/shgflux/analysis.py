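"""Measurement pipeline for SH GUV movies.

Mirrors the experimental analysis chain: locate the equatorial ring, convert
the image to polar coordinates, normalize the per-angle signal by its
cos^2(theta) polarization dependence, keep only an angular acceptance window
around the two polarization-aligned lobes (120 degrees per lobe by default,
avoiding the vanishing-contrast nodes), split the valid arcs into 25 ROIs,
fit each ROI trace with a single exponential I(t) = A exp(-t/tau) + b, and
assemble the decay-constant map along the rim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, optimize

from shgflux.errors import (
    EmptyMapError,
    GeometryError,
    InvalidParameterError,
    NoRingDetectedError,
)
from shgflux.geometry import GUVGeometry
from shgflux.synthetic import SHMovie

#: Angular window retained around each polarization-aligned lobe (degrees).
DEFAULT_ACCEPTANCE_DEG = 120.0
#: Number of angular ROIs along the valid arcs.
DEFAULT_N_ROIS = 25
#: Bins with cos^2(theta - pol) below this are masked to bound the 1/cos^2
#: amplification near the nodes (numerical-stability floor on top of the
#: acceptance window).
COS2_FLOOR = 0.05


@dataclass(frozen=True)
class PolarProfile:
    """Radially integrated per-angle intensity around the ring."""

    theta_grid: np.ndarray  # degrees, uniform bin centers
    intensity: np.ndarray  # per-angle radial integral (counts * px)
    valid_mask: np.ndarray  # bool, bins retained for statistics

    def __post_init__(self) -> None:
        if not (len(self.theta_grid) == len(self.intensity) == len(self.valid_mask)):
            raise InvalidParameterError("profile arrays must share length")

    @property
    def bin_width_deg(self) -> float:
        return 360.0 / len(self.theta_grid)


@dataclass(frozen=True)
class ROITrace:
    """Time trace of the summed normalized intensity in one angular ROI."""

    theta_range: tuple[float, float]  # degrees; end may exceed 360 for wrap
    times: np.ndarray  # s
    intensity: np.ndarray  # counts
    n_pixels: int  # number of polar bins summed

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidParameterError("intensity must be finite")


@dataclass(frozen=True)
class DecayFit:
    """Single-exponential fit I(t) = A exp(-t/tau) + b of one ROI trace."""

    tau: float  # s (inf when no decay)
    amplitude: float  # counts
    baseline: float  # counts
    tau_se: float  # s
    converged: bool
    no_decay: bool


@dataclass(frozen=True)
class DecayMap:
    """Per-ROI decay constants along the rim plus summary statistics."""

    roi_boundaries: list
    fits: list
    summary: dict

    def __post_init__(self) -> None:
        if len(self.roi_boundaries) != len(self.fits):
            raise InvalidParameterError("one fit per ROI required")


# ---------------------------------------------------------------------------
# ring detection
# ---------------------------------------------------------------------------

def _ring_mean(image: np.ndarray, cx: float, cy: float, r_px: float,
               n_samples: int = 360) -> float:
    th = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    xs = cx + r_px * np.cos(th)
    ys = cy - r_px * np.sin(th)
    vals = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
    return float(vals.mean())


def detect_guv(
    image: np.ndarray,
    pixel_size: float,
    psf_fwhm_um: float = 0.4,
    min_radius_px: float = 3.0,
    contrast_sigma: float = 5.0,
) -> GUVGeometry:
    """Locate the GUV ring by maximizing the mean intensity on a circle.

    Strategy: background and robust noise from the image median/MAD; initial
    center from the intensity centroid of the background-subtracted image;
    initial radius from the peak of the radial mean profile; then Nelder-Mead
    refinement of (cx, cy, R) on the bilinearly interpolated circle mean.
    The integration band half-width defaults to twice the PSF FWHM.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InvalidParameterError("image is empty")
    bg = float(np.median(image))
    mad = float(np.median(np.abs(image - bg)))
    noise = max(1.4826 * mad, 1e-12)

    smoothed = ndimage.gaussian_filter(image, sigma=1.0)
    excess = np.clip(smoothed - bg, 0.0, None)
    total = excess.sum()
    if total <= 0:
        raise NoRingDetectedError("no intensity above background")
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx0 = float((excess * xx).sum() / total)
    cy0 = float((excess * yy).sum() / total)

    r_max = min(cx0, cy0, w - 1 - cx0, h - 1 - cy0)
    radii = np.arange(min_radius_px, max(r_max, min_radius_px + 1.0), 0.5)
    profile = np.array([_ring_mean(smoothed, cx0, cy0, r) for r in radii])
    best = int(np.argmax(profile))
    if profile[best] - bg < contrast_sigma * noise:
        raise NoRingDetectedError("no ring with contrast above threshold")
    r0 = float(radii[best])

    def objective(p):
        cx, cy, r = p
        if r < min_radius_px:
            return 0.0
        return -_ring_mean(image, cx, cy, r)

    res = optimize.minimize(
        objective,
        x0=[cx0, cy0, r0],
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-9, "maxiter": 600},
    )
    cx, cy, r_px = res.x
    return GUVGeometry(
        center=(float(cx), float(cy)),
        radius_um=float(r_px) * pixel_size,
        band_halfwidth_um=2.0 * psf_fwhm_um,
        pixel_size_um=pixel_size,
    )


# ---------------------------------------------------------------------------
# polar transform and normalization
# ---------------------------------------------------------------------------

def polar_transform(
    image: np.ndarray,
    geometry: GUVGeometry,
    n_theta: int = 360,
    dr_px: float = 0.25,
) -> PolarProfile:
    """Radially integrate the ring band into a per-angle intensity profile.

    Each angular bin holds the integral of the bilinearly interpolated image
    over r in [R - band, R + band], with the polar area element r dr, so the
    profile times the angular bin width (radians) conserves the
    band-integrated image intensity.
    """
    image = np.asarray(image, dtype=float)
    r_in = geometry.radius_px - geometry.band_halfwidth_px
    r_out = geometry.radius_px + geometry.band_halfwidth_px
    if r_in <= 0:
        raise GeometryError("integration band reaches the ring center")
    if not geometry.fits_inside(image.shape):
        raise GeometryError("integration band exceeds image bounds")
    theta = np.arange(n_theta) * (360.0 / n_theta)
    radii = np.arange(r_in, r_out + 0.5 * dr_px, dr_px)
    cx, cy = geometry.center
    tt = np.radians(theta)[:, None]
    rr = radii[None, :]
    xs = cx + rr * np.cos(tt)
    ys = cy - rr * np.sin(tt)
    vals = ndimage.map_coordinates(image, [ys.ravel(), xs.ravel()], order=1)
    vals = vals.reshape(n_theta, len(radii))
    intensity = (vals * rr).sum(axis=1) * dr_px
    return PolarProfile(
        theta_grid=theta,
        intensity=intensity,
        valid_mask=np.ones(n_theta, dtype=bool),
    )


def _angular_distance(a_deg, b_deg):
    d = np.abs((np.asarray(a_deg) - b_deg + 180.0) % 360.0 - 180.0)
    return d


def normalize_polarization(
    profile: PolarProfile,
    polarization_angle: float,
    acceptance_angle: float = DEFAULT_ACCEPTANCE_DEG,
    cos2_floor: float = COS2_FLOOR,
) -> PolarProfile:
    """Divide out the cos^2 polarization dependence and mask the nodes.

    Bins within ``acceptance_angle/2`` of either polarization-aligned lobe
    (at the polarization angle and its antipode) are retained, so the two
    arcs together cover ``2 * acceptance_angle`` of the circle; bins with
    cos^2 below ``cos2_floor`` are additionally masked to bound the
    normalization amplification.
    """
    if not (0.0 < acceptance_angle <= 180.0):
        raise InvalidParameterError("acceptance_angle must be in (0, 180]")
    theta = profile.theta_grid
    c2 = np.cos(np.radians(theta - polarization_angle)) ** 2
    half = acceptance_angle / 2.0
    d1 = _angular_distance(theta, polarization_angle)
    d2 = _angular_distance(theta, polarization_angle + 180.0)
    in_window = (d1 <= half) | (d2 <= half)
    usable = c2 >= cos2_floor
    mask = profile.valid_mask & in_window & usable
    intensity = np.where(usable, profile.intensity / np.where(usable, c2, 1.0),
                         profile.intensity)
    return PolarProfile(theta_grid=theta, intensity=intensity, valid_mask=mask)


# ---------------------------------------------------------------------------
# ROI segmentation and trace extraction
# ---------------------------------------------------------------------------

def _valid_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs on the circle as (start_index, length)."""
    n = len(mask)
    if mask.all():
        return [(0, n)]
    if not mask.any():
        return []
    # rotate so the array starts on a False bin; runs then do not wrap
    start = int(np.argmin(mask))
    rolled = np.roll(mask, -start)
    runs = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            runs.append(((i + start) % n, j - i))
            i = j
        else:
            i += 1
    return runs


def segment_rois(profile: PolarProfile, n_rois: int = DEFAULT_N_ROIS) -> list:
    """Partition the valid arcs into contiguous equal-angle ROIs.

    ROIs never span masked regions.  ROI counts are allocated to the valid
    runs by largest remainder on run length; ``n_rois = 1`` returns a single
    ROI covering the largest contiguous valid span.  Returns a list of
    (theta_start, theta_end) tuples in degrees (end may exceed 360 on wrap).
    """
    if n_rois < 1:
        raise InvalidParameterError("n_rois must be >= 1")
    runs = _valid_runs(profile.valid_mask)
    if not runs:
        raise InvalidParameterError("no valid bins to segment")
    total_bins = sum(length for _, length in runs)
    if n_rois > total_bins:
        raise InvalidParameterError("n_rois exceeds the number of valid bins")
    width = profile.bin_width_deg
    if n_rois == 1:
        start, length = max(runs, key=lambda r: r[1])
        return [(start * width, (start + length) * width)]
    # largest-remainder allocation, at least one ROI per run while possible
    quotas = [n_rois * length / total_bins for _, length in runs]
    counts = [int(q) for q in quotas]
    remainder = n_rois - sum(counts)
    order = np.argsort([c - q for q, c in zip(quotas, counts)])
    for idx in order[:remainder]:
        counts[idx] += 1
    # never allocate more ROIs to a run than it has bins
    for i, (_, length) in enumerate(runs):
        if counts[i] > length:
            excess = counts[i] - length
            counts[i] = length
            for j in range(len(runs)):
                if j != i and counts[j] < runs[j][1]:
                    take = min(excess, runs[j][1] - counts[j])
                    counts[j] += take
                    excess -= take
                    if excess == 0:
                        break
    ranges = []
    for (start, length), k in zip(runs, counts):
        if k == 0:
            continue
        edges = np.linspace(0, length, k + 1)
        for a, b in zip(edges[:-1], edges[1:]):
            ranges.append(((start + a) * width, (start + b) * width))
    return ranges


def roi_member_bins(profile: PolarProfile, theta_range) -> np.ndarray:
    """Indices of valid bins whose centers fall in [start, end) (circular)."""
    start, end = theta_range
    span = end - start
    rel = (profile.theta_grid - start) % 360.0
    member = rel < span - 1e-9
    # include the bin sitting exactly on the start edge
    member |= np.isclose(rel, 0.0)
    return np.where(member & profile.valid_mask)[0]


def estimate_background(image: np.ndarray, geometry: GUVGeometry) -> float:
    """Median counts outside the ring band (annulus r > R + 3*band)."""
    h, w = image.shape
    cx, cy = geometry.center
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - cx, yy - cy)
    outer = r > geometry.radius_px + 3.0 * geometry.band_halfwidth_px
    if outer.sum() < 16:
        inner = r < geometry.radius_px - 3.0 * geometry.band_halfwidth_px
        outer = outer | inner
    if outer.sum() < 4:
        return float(np.median(image))
    return float(np.median(image[outer]))


def _frame_profile(frame, geometry, polarization_angle, acceptance_angle,
                   n_theta, subtract_background):
    work = frame
    if subtract_background:
        work = frame - estimate_background(frame, geometry)
    prof = polar_transform(work, geometry, n_theta=n_theta)
    return normalize_polarization(prof, polarization_angle, acceptance_angle)


def extract_traces(
    movie: SHMovie,
    geometry: GUVGeometry,
    rois,
    polarization_angle: float | None = None,
    acceptance_angle: float = DEFAULT_ACCEPTANCE_DEG,
    n_theta: int = 360,
    subtract_background: bool = True,
):
    """Per-ROI and whole-GUV time traces of normalized polar intensity.

    Returns ``(roi_traces, whole_trace)``.  The whole-GUV trace sums every
    valid bin; ROI traces sum the valid bins inside each angular range, so
    the whole trace equals the ROI sum whenever the ROIs tile the valid arcs.
    """
    if polarization_angle is None:
        polarization_angle = movie.optics.polarization_angle
    profiles = [
        _frame_profile(frame, geometry, polarization_angle, acceptance_angle,
                       n_theta, subtract_background)
        for frame in movie.frames
    ]
    times = np.asarray(movie.timestamps, dtype=float)
    members = [roi_member_bins(profiles[0], rng) for rng in rois]
    roi_traces = []
    for rng_deg, bins in zip(rois, members):
        vals = np.array([p.intensity[bins].sum() for p in profiles])
        roi_traces.append(
            ROITrace(theta_range=tuple(rng_deg), times=times, intensity=vals,
                     n_pixels=len(bins))
        )
    valid = profiles[0].valid_mask
    whole_vals = np.array([p.intensity[valid].sum() for p in profiles])
    whole = ROITrace(theta_range=(0.0, 360.0), times=times,
                     intensity=whole_vals, n_pixels=int(valid.sum()))
    return roi_traces, whole


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

def _exp_model(t, a, tau, b):
    return a * np.exp(-t / tau) + b


def _loglinear_init(t, y):
    """Initial (A, tau, b) from a log-linear regression of the trace head."""
    b0 = float(np.percentile(y, 10))
    z = y - b0
    a0 = max(float(z[0]), 1e-12)
    head = z > 0.2 * a0
    if head.sum() >= 3:
        th, zh = t[head], z[head]
        slope, intercept = np.polyfit(th, np.log(np.clip(zh, 1e-12, None)), 1)
        if slope < 0:
            return math.exp(intercept), -1.0 / slope, b0
    span = t[-1] - t[0]
    return a0, max(span / 3.0, 1e-9), b0


def fit_decay(
    trace: ROITrace,
    no_decay_amplitude_frac: float = 0.1,
    no_decay_tau_factor: float = 50.0,
    var_floor_frac: float = 0.02,
) -> DecayFit:
    """Weighted least-squares exponential fit of one ROI trace.

    Weights approximate Poisson counting statistics (sigma_i proportional to
    sqrt(I_i)) with the variance floored at ``var_floor_frac`` of the trace
    maximum: integrated/normalized intensities are not raw photon counts, and
    near-zero tail points otherwise acquire unbounded weight while their
    scatter is in truth dominated by additive background/read noise.
    Initialization comes from a log-linear regression of
    the background-subtracted head of the trace; up to four restarts rescale
    the initial tau.  ``no_decay`` is flagged when the fitted relative
    amplitude A/(A+b) falls below ``no_decay_amplitude_frac`` or the fitted
    tau exceeds ``no_decay_tau_factor`` times the observation span.
    """
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.intensity, dtype=float)
    if len(t) < 5:
        raise InvalidParameterError("need at least 5 time points to fit")
    span = float(t[-1] - t[0])
    scale = float(np.max(np.abs(y))) or 1.0

    # a trace with essentially no structure is flat by inspection
    if np.ptp(y) <= 1e-12 * scale:
        return DecayFit(tau=math.inf, amplitude=0.0, baseline=float(np.mean(y)),
                        tau_se=0.0, converged=True, no_decay=True)

    a0, tau0, b0 = _loglinear_init(t, y)
    sigma = np.sqrt(np.clip(y, var_floor_frac * scale, None))
    tau_cap = no_decay_tau_factor * span * 20.0
    best = None
    for factor in (1.0, 0.3, 3.0, 10.0):
        try:
            popt, pcov = optimize.curve_fit(
                _exp_model,
                t,
                y,
                p0=[max(a0, 1e-9 * scale), min(max(tau0 * factor, span * 1e-3),
                                               tau_cap), b0],
                sigma=sigma,
                absolute_sigma=False,
                bounds=([0.0, span * 1e-4, -np.inf], [np.inf, tau_cap, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = float(np.sum(((y - _exp_model(t, *popt)) / sigma) ** 2))
        if best is None or resid < best[2]:
            best = (popt, pcov, resid)
    if best is None:
        return DecayFit(tau=math.nan, amplitude=math.nan, baseline=math.nan,
                        tau_se=math.nan, converged=False, no_decay=False)
    (a, tau, b), pcov, _ = best
    var = pcov[1, 1] if np.all(np.isfinite(pcov)) else math.inf
    tau_se = float(math.sqrt(var)) if var >= 0 else math.inf
    rel_amp = a / (a + b) if (a + b) > 0 else 0.0
    no_decay = (rel_amp < no_decay_amplitude_frac) or (tau > no_decay_tau_factor * span)
    if no_decay:
        return DecayFit(tau=math.inf, amplitude=float(a), baseline=float(b),
                        tau_se=tau_se, converged=True, no_decay=True)
    return DecayFit(tau=float(tau), amplitude=float(a), baseline=float(b),
                    tau_se=tau_se, converged=True, no_decay=False)


def build_decay_map(fits, rois) -> DecayMap:
    """Assemble per-ROI fits into a rim decay map with summary statistics."""
    fits = list(fits)
    rois = list(rois)
    if len(fits) != len(rois):
        raise InvalidParameterError("one fit per ROI required")
    if not any(f.converged for f in fits):
        raise EmptyMapError("all ROI fits failed")
    finite = [f.tau for f in fits
              if f.converged and not f.no_decay and math.isfinite(f.tau)]
    if finite:
        summary = {
            "n_rois": len(fits),
            "n_finite": len(finite),
            "tau_mean_s": float(np.mean(finite)),
            "tau_min_s": float(np.min(finite)),
            "tau_max_s": float(np.max(finite)),
            "tau_ratio": float(np.max(finite) / np.min(finite)),
        }
    else:
        summary = {
            "n_rois": len(fits),
            "n_finite": 0,
            "tau_mean_s": math.nan,
            "tau_min_s": math.nan,
            "tau_max_s": math.nan,
            "tau_ratio": math.nan,
        }
    return DecayMap(roi_boundaries=rois, fits=fits, summary=summary)


# ---------------------------------------------------------------------------
# noise floor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseFloorCrossing:
    time_s: float
    censored: bool


def time_to_noise_floor(trace: ROITrace, noise_level: float,
                        window: int = 3) -> NoiseFloorCrossing:
    """First timestamp at which the running mean drops to the noise floor.

    A centered ``window``-frame running mean suppresses single-frame noise
    excursions; if the mean never reaches ``noise_level`` the crossing is
    censored (``time_s`` is NaN).
    """
    if noise_level < 0:
        raise InvalidParameterError("noise_level must be >= 0")
    y = np.asarray(trace.intensity, dtype=float)
    t = np.asarray(trace.times, dtype=float)
    if len(y) < window:
        raise InvalidParameterError("trace shorter than the running-mean window")
    kernel = np.ones(window) / window
    rm = np.convolve(y, kernel, mode="valid")
    tm = t[(window - 1) // 2 : (window - 1) // 2 + len(rm)]
    below = np.where(rm <= noise_level)[0]
    if len(below) == 0:
        return NoiseFloorCrossing(time_s=math.nan, censored=True)
    return NoiseFloorCrossing(time_s=float(tm[below[0]]), censored=False)


def relative_frame_noise(trace: ROITrace) -> float:
    """Robust per-frame relative scatter of a trace around its local trend.

    Each point is divided by the centered 3-frame running mean; for a smooth
    (even exponentially decaying) trend that ratio is locally constant, so
    its scaled median absolute deviation estimates the frame-to-frame
    multiplicative noise without being biased by the decay itself.
    """
    y = np.asarray(trace.intensity, dtype=float)
    if len(y) < 5:
        raise InvalidParameterError("need at least 5 frames")
    rm = np.convolve(y, np.ones(3) / 3.0, mode="valid")
    ratio = y[1:-1] / np.where(rm == 0.0, 1.0, rm)
    dev = np.abs(ratio - np.median(ratio))
    return float(1.4826 * np.median(dev))


def estimate_noise_floor(
    movie: SHMovie,
    geometry: GUVGeometry,
    trace: ROITrace | None = None,
    polarization_angle: float | None = None,
    acceptance_angle: float = DEFAULT_ACCEPTANCE_DEG,
    n_theta: int = 360,
    control_radius_factor: float = 0.5,
    n_sigma: float = 3.0,
    subtract_background: bool = True,
) -> float:
    """Noise floor of the integrated trace (analogue of the dashed
    noise-level line on an integrated-intensity plot).

    Two measured components are combined (maximum of the two):

    * camera floor — the identical integration (band width, acceptance mask,
      cos^2 normalization) applied on a signal-free control circle at
      ``control_radius_factor * R`` inside the GUV gives the additive
      background/read-noise level: mean + ``n_sigma`` SD over frames, scaled
      by the ring-radius ratio;
    * illumination floor — the integrated SH signal of a single GUV also
      scatters by a frame-correlated factor (laser fluctuations); below
      ``n_sigma`` times that relative scatter of the initial intensity a
      decayed signal is indistinguishable from a fluctuation.  Estimated
      from the detrended whole-GUV trace when ``trace`` is given.
    """
    control = GUVGeometry(
        center=geometry.center,
        radius_um=geometry.radius_um * control_radius_factor,
        band_halfwidth_um=geometry.band_halfwidth_um,
        pixel_size_um=geometry.pixel_size_um,
    )
    if polarization_angle is None:
        polarization_angle = movie.optics.polarization_angle
    vals = []
    for frame in movie.frames:
        prof = _frame_profile(frame, control, polarization_angle,
                              acceptance_angle, n_theta, subtract_background)
        vals.append(prof.intensity[prof.valid_mask].sum())
    vals = np.asarray(vals)
    # rescale control-band area to the measurement band: the radial integral
    # carries the polar area element r dr, so counts scale with the ring radius
    area_ratio = geometry.radius_px / control.radius_px
    floor = (vals.mean() + n_sigma * vals.std(ddof=1)) * area_ratio
    if trace is not None:
        rel = relative_frame_noise(trace)
        i0 = float(np.mean(trace.intensity[:3]))
        floor = max(floor, n_sigma * rel * i0)
    return float(floor)
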