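"""Measurement chain: detection, polar transform, normalization, fits, maps."""

import math

import numpy as np
import pytest

from shgflux.analysis import (
    NoiseFloorCrossing,
    PolarProfile,
    ROITrace,
    build_decay_map,
    detect_guv,
    estimate_noise_floor,
    extract_traces,
    fit_decay,
    normalize_polarization,
    polar_transform,
    relative_frame_noise,
    roi_member_bins,
    segment_rois,
    time_to_noise_floor,
)
from shgflux.errors import EmptyMapError, InvalidParameterError, NoRingDetectedError
from shgflux.geometry import GUVGeometry
from shgflux.streams import substream
from shgflux.synthetic import (
    PRESETS,
    OpticsConfig,
    default_geometry,
    default_schedule,
    generate_movie,
    render_frame,
)


class TestDetectGUV:
    def test_noise_free_ring_recovered(self, optics, geometry):
        img = render_frame(geometry, np.ones(360), optics, noise=False)
        det = detect_guv(img, optics.pixel_size)
        assert abs(det.center[0] - geometry.center[0]) < 1.0
        assert abs(det.center[1] - geometry.center[1]) < 1.0
        assert det.radius_um == pytest.approx(geometry.radius_um, rel=0.02)

    def test_uniform_image_raises(self, optics):
        with pytest.raises(NoRingDetectedError):
            detect_guv(np.full((64, 64), 100.0), optics.pixel_size)

    def test_center_within_two_pixels_at_snr20_over_100_seeds(self, optics, geometry):
        """Monte Carlo: ring at crest SNR ~ 20, detection within 2 px."""
        errs = []
        for seed in range(100):
            img = render_frame(geometry, np.ones(360), optics, seed=seed)
            det = detect_guv(img, optics.pixel_size)
            errs.append(math.hypot(det.center[0] - geometry.center[0],
                                   det.center[1] - geometry.center[1]))
        assert max(errs) < 2.0


@pytest.fixture(scope="module")
def fine_setup():
    """Well-sampled ring (0.1 um px) for quantitative checks."""
    optics = OpticsConfig(pixel_size=0.1, psf_fwhm=0.4, polarization_angle=90.0)
    geo = GUVGeometry(center=(63.5, 63.5), radius_um=4.0,
                      band_halfwidth_um=0.8, pixel_size_um=0.1)
    img = render_frame(geo, np.ones(360), optics, shape=(128, 128),
                       noise=False) - optics.background_level
    return optics, geo, img


class TestPolarTransform:
    def test_cos2_extrema_locations(self, fine_setup):
        optics, geo, img = fine_setup
        prof = polar_transform(img, geo, n_theta=360)
        top = set(np.argsort(prof.intensity)[-10:])
        assert any(abs((t - 90) % 360) <= 3 or abs((t - 270) % 360) <= 3
                   for t in top)
        node_vals = prof.intensity[[0, 180]]
        assert np.all(node_vals < 0.02 * prof.intensity.max())

    def test_intensity_conservation(self, fine_setup):
        _, geo, img = fine_setup
        prof = polar_transform(img, geo, n_theta=720)
        total_polar = prof.intensity.sum() * math.radians(prof.bin_width_deg)
        yy, xx = np.mgrid[0:128, 0:128]
        rr = np.hypot(xx - geo.center[0], yy - geo.center[1])
        annulus = ((rr >= geo.radius_px - geo.band_halfwidth_px)
                   & (rr <= geo.radius_px + geo.band_halfwidth_px))
        assert total_polar == pytest.approx(img[annulus].sum(), rel=0.02)

    def test_rotationally_symmetric_ring_is_flat(self, fine_setup):
        """cos^2-normalizing an exactly cos^2-modulated ring gives a constant."""
        optics, geo, img = fine_setup
        prof = normalize_polarization(polar_transform(img, geo, n_theta=360),
                                      optics.polarization_angle)
        vals = prof.intensity[prof.valid_mask]
        assert np.abs(vals / vals.mean() - 1.0).max() < 0.01

    def test_band_outside_image_raises(self, optics):
        geo = GUVGeometry(center=(5.0, 5.0), radius_um=10.0,
                          band_halfwidth_um=0.8, pixel_size_um=0.4)
        with pytest.raises(Exception):
            polar_transform(np.zeros((64, 64)), geo)


class TestNormalizePolarization:
    @pytest.fixture()
    def flat_profile(self):
        theta = np.arange(360.0)
        return PolarProfile(theta_grid=theta, intensity=np.ones(360),
                            valid_mask=np.ones(360, dtype=bool))

    def test_lobe_center_unchanged_and_60deg_quadrupled(self, flat_profile):
        out = normalize_polarization(flat_profile, polarization_angle=90.0)
        assert out.intensity[90] == pytest.approx(1.0, rel=1e-12)
        assert out.intensity[150] == pytest.approx(4.0, rel=1e-12)

    def test_node_masked_under_120deg_acceptance(self, flat_profile):
        out = normalize_polarization(flat_profile, polarization_angle=90.0,
                                     acceptance_angle=120.0)
        assert not out.valid_mask[0]  # 90 deg from the lobe
        assert out.valid_mask[90] and out.valid_mask[270]
        # two retained arcs cover 2 * acceptance of the circle
        assert out.valid_mask.sum() == pytest.approx(242, abs=2)

    def test_acceptance_angle_validation(self, flat_profile):
        with pytest.raises(InvalidParameterError):
            normalize_polarization(flat_profile, 90.0, acceptance_angle=0.0)


class TestSegmentROIs:
    @pytest.fixture()
    def masked_profile(self):
        theta = np.arange(360.0)
        prof = PolarProfile(theta_grid=theta, intensity=np.ones(360),
                            valid_mask=np.ones(360, dtype=bool))
        return normalize_polarization(prof, polarization_angle=90.0)

    def test_default_25_rois(self, masked_profile):
        rois = segment_rois(masked_profile, 25)
        assert len(rois) == 25

    def test_partition_covers_each_valid_bin_once(self, masked_profile):
        rois = segment_rois(masked_profile, 25)
        counts = np.zeros(360, dtype=int)
        for rng in rois:
            counts[roi_member_bins(masked_profile, rng)] += 1
        assert np.all(counts[masked_profile.valid_mask] == 1)
        assert np.all(counts[~masked_profile.valid_mask] == 0)

    def test_single_roi_covers_largest_valid_run(self, masked_profile):
        rois = segment_rois(masked_profile, 1)
        assert len(rois) == 1
        bins = roi_member_bins(masked_profile, rois[0])
        # each lobe arc spans ~121 bins; one ROI covers one full arc
        assert len(bins) >= 120

    def test_too_many_rois_raises(self, masked_profile):
        with pytest.raises(InvalidParameterError):
            segment_rois(masked_profile, 10_000)


class TestExtractTraces:
    def test_static_movie_constant_traces(self, optics, geometry, dopc_movie):
        from shgflux.synthetic import SHMovie

        frames = np.repeat(dopc_movie.frames[:1], 6, axis=0)
        static = SHMovie(frames=frames, timestamps=np.arange(6.0) * 60.0,
                         optics=optics)
        prof = normalize_polarization(
            polar_transform(frames[0], geometry), optics.polarization_angle)
        rois = segment_rois(prof, 10)
        traces, whole = extract_traces(static, geometry, rois)
        for tr in traces + [whole]:
            assert np.allclose(tr.intensity, tr.intensity[0])

    def test_whole_trace_equals_sum_of_rois(self, dopc_analysis):
        total = np.sum([tr.intensity for tr in dopc_analysis["traces"]], axis=0)
        assert np.allclose(total, dopc_analysis["whole"].intensity, rtol=1e-9)

    def test_dopc_trace_tracks_truth_envelope(self, dopc_movie, dopc_analysis):
        whole = dopc_analysis["whole"]
        tf = dopc_movie.truth.tau_field
        mask = dopc_analysis["profile"].valid_mask
        envelope = np.array([
            np.mean(np.exp(-t / tf.tau[mask])) for t in whole.times
        ])
        measured = whole.intensity / whole.intensity[0]
        # integrated trace follows the mean intensity envelope within noise
        assert np.all(np.diff(measured) < 0.05)
        assert np.abs(measured - envelope / envelope[0]).max() < 0.15


class TestFitDecay:
    def test_noiseless_exponential_exact(self):
        t = np.arange(30.0) * 60.0
        y = 500.0 * np.exp(-t / 240.0) + 50.0
        fit = fit_decay(ROITrace(theta_range=(0, 10), times=t, intensity=y,
                                 n_pixels=4))
        assert fit.converged and not fit.no_decay
        assert fit.tau == pytest.approx(240.0, rel=1e-6)

    def test_constant_trace_flags_no_decay(self):
        t = np.arange(10.0) * 60.0
        fit = fit_decay(ROITrace(theta_range=(0, 10), times=t,
                                 intensity=np.full(10, 321.0), n_pixels=4))
        assert fit.no_decay and fit.converged

    @pytest.mark.parametrize("tau", [240.0, 780.0])
    def test_monte_carlo_recovery_under_multiplicative_noise(self, tau):
        """200 replicates, 5% noise, 30 points over 30 min: unbiased recovery."""
        t = np.arange(30.0) * 60.0
        estimates = []
        for rep in range(200):
            rng = substream(77, "fitmc", int(tau), rep)
            y = (1000.0 * np.exp(-t / tau) + 100.0) \
                * (1.0 + 0.05 * rng.standard_normal(30))
            fit = fit_decay(ROITrace(theta_range=(0, 10), times=t, intensity=y,
                                     n_pixels=4))
            assert fit.converged
            estimates.append(fit.tau)
        estimates = np.array(estimates)
        assert np.median(estimates) == pytest.approx(tau, rel=0.05)
        assert np.mean(np.abs(estimates - tau) / tau < 0.20) >= 0.90

    def test_too_few_points_raises(self):
        t = np.arange(4.0)
        with pytest.raises(InvalidParameterError):
            fit_decay(ROITrace(theta_range=(0, 10), times=t,
                               intensity=np.ones(4), n_pixels=1))


class TestDecayMap:
    def test_equal_taus_give_unit_ratio(self):
        t = np.arange(30.0) * 60.0
        y = 500.0 * np.exp(-t / 300.0) + 10.0
        fits = [fit_decay(ROITrace(theta_range=(i, i + 10), times=t,
                                   intensity=y, n_pixels=4)) for i in range(5)]
        dmap = build_decay_map(fits, [(i, i + 10) for i in range(5)])
        assert dmap.summary["tau_ratio"] == pytest.approx(1.0, rel=1e-6)

    def test_all_failed_raises_empty_map(self):
        from shgflux.analysis import DecayFit

        bad = DecayFit(tau=math.nan, amplitude=math.nan, baseline=math.nan,
                       tau_se=math.nan, converged=False, no_decay=False)
        with pytest.raises(EmptyMapError):
            build_decay_map([bad, bad], [(0, 10), (10, 20)])

    def test_masked_bins_do_not_influence_results(self, optics, geometry):
        """Perturbing masked-out pixels leaves the decay map unchanged."""
        movie = generate_movie(PRESETS["DOPC:DOPA"], geometry, optics,
                               default_schedule(12, 60.0), seed=21)
        prof = normalize_polarization(
            polar_transform(movie.frames[0], geometry),
            optics.polarization_angle)
        rois = segment_rois(prof, 10)

        def summarize(frames):
            from shgflux.synthetic import SHMovie

            mv = SHMovie(frames=frames, timestamps=movie.timestamps,
                         optics=optics)
            traces, _ = extract_traces(mv, geometry, rois,
                                       subtract_background=False)
            return [fit_decay(tr).tau for tr in traces]

        ref = summarize(movie.frames)
        # corrupt pixels along the node directions (masked arcs), outside
        # every accepted bin
        corrupted = movie.frames.copy()
        cx, cy = geometry.center
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        theta = np.degrees(np.arctan2(-(yy - cy), xx - cx)) % 360.0
        node = (np.abs((theta - 0.0 + 90) % 180 - 90) < 20)
        corrupted[:, node] += 1e4
        assert np.allclose(summarize(corrupted), ref, rtol=1e-9)


class TestNoiseFloor:
    def test_flat_trace_is_censored(self):
        t = np.arange(10.0) * 60.0
        tr = ROITrace(theta_range=(0, 360), times=t,
                      intensity=np.full(10, 500.0), n_pixels=9)
        out = time_to_noise_floor(tr, 100.0)
        assert out.censored and math.isnan(out.time_s)

    def test_crossing_matches_closed_form_for_clean_exponential(self):
        tau, a, b, level = 300.0, 1000.0, 20.0, 120.0
        t = np.arange(0.0, 2400.0, 10.0)
        tr = ROITrace(theta_range=(0, 360), times=t,
                      intensity=a * np.exp(-t / tau) + b, n_pixels=9)
        out = time_to_noise_floor(tr, level)
        expected = tau * math.log(a / (level - b))
        assert not out.censored
        assert out.time_s == pytest.approx(expected, abs=15.0)

    def test_relative_frame_noise_tracks_flicker(self, optics, geometry):
        movie = generate_movie(PRESETS["SLPC:SLPA"], geometry, optics,
                               default_schedule(30, 60.0), seed=31)
        prof = normalize_polarization(
            polar_transform(movie.frames[0], geometry),
            optics.polarization_angle)
        rois = segment_rois(prof, 5)
        _, whole = extract_traces(movie, geometry, rois)
        rel = relative_frame_noise(whole)
        assert 0.3 * optics.flicker_rel_sd < rel < 3.0 * optics.flicker_rel_sd

    def test_negative_level_rejected(self):
        t = np.arange(5.0)
        tr = ROITrace(theta_range=(0, 1), times=t, intensity=np.ones(5),
                      n_pixels=1)
        with pytest.raises(InvalidParameterError):
            time_to_noise_floor(tr, -1.0)


class TestEndToEnd:
    def test_median_tau_recovery_within_10pct(self, dopc_movie, dopc_analysis):
        tf = dopc_movie.truth.tau_field
        prof = dopc_analysis["profile"]
        errs = []
        for rng, fit in zip(dopc_analysis["rois"], dopc_analysis["fits"]):
            if not fit.converged or fit.no_decay:
                continue
            bins = roi_member_bins(prof, rng)
            truth = float(np.exp(np.mean(np.log(tf.tau[bins]))))
            errs.append(abs(fit.tau - truth) / truth)
        assert len(errs) >= 20
        assert np.median(errs) <= 0.10

    def test_flat_composition_false_positive_rate(self, optics, geometry):
        """Across 50 seeded flat-membrane movies, <= 5% of ROIs show decay."""
        flags = []
        for seed in range(50):
            movie = generate_movie(PRESETS["DPhPC:DPhPA"], geometry, optics,
                                   default_schedule(12, 60.0), seed=seed)
            prof = normalize_polarization(
                polar_transform(movie.frames[0], geometry),
                optics.polarization_angle)
            rois = segment_rois(prof, 25)
            traces, _ = extract_traces(movie, geometry, rois)
            flags.extend(not fit_decay(tr).no_decay for tr in traces)
        assert np.mean(flags) <= 0.05
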