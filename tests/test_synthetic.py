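"""Ground-truth generator: tau fields, asymmetry envelopes, rendering, movies."""

import math

import numpy as np
import pytest
from scipy import optimize

from shgflux.errors import GeometryError, InvalidParameterError
from shgflux.geometry import GUVGeometry
from shgflux.streams import substream
from shgflux.synthetic import (
    PRESETS,
    CompositionPreset,
    OpticsConfig,
    default_geometry,
    default_schedule,
    generate_movie,
    make_tau_field,
    render_frame,
    simulate_asymmetry,
)


class TestTauField:
    def test_threefold_heterogeneity_exact_rescale(self):
        field = make_tau_field(PRESETS["DOPC:DOPA"], n_theta=360, seed=1)
        ratio = field.tau.max() / field.tau.min()
        assert ratio == pytest.approx(3.0, rel=0.10)
        # defaults span roughly the printed 4-13 min ROI fit range
        assert 200.0 < field.tau.min() < 300.0
        assert 650.0 < field.tau.max() < 820.0

    @pytest.mark.parametrize("name", ["DPhPC:DPhPA", "SLPC:SLPA"])
    def test_non_translocating_presets_are_infinite(self, name):
        field = make_tau_field(PRESETS[name], n_theta=64, seed=0)
        assert np.all(np.isinf(field.tau))

    def test_homogeneous_limit(self):
        preset = CompositionPreset(name="x", tau_base=300.0, tau_spatial_ratio=1.0,
                                   domain_correlation_length=2.0, sigma=1e-3)
        field = make_tau_field(preset, n_theta=90, seed=5)
        assert np.allclose(field.tau, 300.0)

    def test_periodic_continuity(self):
        field = make_tau_field(PRESETS["DOPC:DOPA"], n_theta=720, seed=2)
        # adjacent bins across the 0/360 seam differ like any other neighbors
        seam = abs(math.log(field.tau[0] / field.tau[-1]))
        typical = np.abs(np.diff(np.log(field.tau))).max()
        assert seam <= typical * 1.5

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            make_tau_field(PRESETS["DOPC:DOPA"], n_theta=4, seed=0)
        with pytest.raises(InvalidParameterError):
            CompositionPreset(name="bad", tau_base=300.0, tau_spatial_ratio=3.0,
                              domain_correlation_length=-1.0, sigma=1e-3)


class TestAsymmetry:
    def test_normalization_and_limits(self):
        field = make_tau_field(PRESETS["DOPC:DOPA"], n_theta=64, seed=4)
        t = np.arange(0.0, 1800.0, 60.0)
        asym = simulate_asymmetry(field, t)
        assert np.allclose(asym.asymmetry[0], 1.0)
        assert np.all(asym.asymmetry <= 1.0) and np.all(asym.asymmetry >= 0.0)
        assert np.all(np.diff(asym.asymmetry, axis=0) <= 0)

    def test_infinite_tau_never_decays(self):
        field = make_tau_field(PRESETS["DPhPC:DPhPA"], n_theta=32, seed=0)
        asym = simulate_asymmetry(field, np.array([0.0, 600.0, 3600.0]))
        assert np.allclose(asym.asymmetry, 1.0)

    def test_intensity_envelope_reaches_1_over_e_at_tau(self):
        preset = CompositionPreset(name="x", tau_base=240.0, tau_spatial_ratio=1.0,
                                   domain_correlation_length=2.0, sigma=1e-3)
        field = make_tau_field(preset, n_theta=16, seed=0)
        asym = simulate_asymmetry(field, np.array([0.0, 240.0]))
        intensity_env = asym.asymmetry[1] ** 2
        assert intensity_env == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_time_grid_validation(self):
        field = make_tau_field(PRESETS["DOPC:DOPA"], n_theta=16, seed=0)
        with pytest.raises(InvalidParameterError):
            simulate_asymmetry(field, np.array([60.0, 120.0]))  # no t = 0
        with pytest.raises(InvalidParameterError):
            simulate_asymmetry(field, np.array([0.0, -5.0]))


class TestRenderFrame:
    def test_cos2_node_is_pure_background(self, optics, geometry):
        img = render_frame(geometry, np.ones(360), optics, noise=False)
        cx, cy = geometry.center
        # polarization is vertical (90 deg): nodes lie along the x axis
        node = img[int(round(cy)), int(round(cx + geometry.radius_px))]
        crest = img[int(round(cy - geometry.radius_px)), int(round(cx))]
        # nearest pixel center sits 0.5 px off the exact node direction
        assert node == pytest.approx(optics.background_level, abs=0.5)
        # crest pixel also sits ~0.5 px off the exact ring radius
        assert crest > optics.background_level + 0.3 * optics.peak_counts

    def test_exposure_linearity(self, geometry):
        a = np.ones(360)
        o1 = OpticsConfig(exposure=5.0)
        o2 = OpticsConfig(exposure=10.0)
        img1 = render_frame(geometry, a, o1, noise=False) - o1.background_level
        img2 = render_frame(geometry, a, o2, noise=False) - o2.background_level
        assert np.allclose(img2, 2.0 * img1)

    def test_radial_fwhm_matches_psf(self):
        # integer-pixel center so one pixel column passes exactly through it
        optics = OpticsConfig(polarization_angle=90.0)
        geo = GUVGeometry(center=(32.0, 32.0), radius_um=10.0,
                          band_halfwidth_um=0.8, pixel_size_um=0.4)
        img = render_frame(geo, np.ones(360), optics, shape=(66, 66),
                           noise=False) - optics.background_level
        r = 32.0 - np.arange(66.0)
        sel = (r > 15) & (r < 35)

        def gauss(rr, a, r0, s):
            return a * np.exp(-0.5 * ((rr - r0) / s) ** 2)

        popt, _ = optimize.curve_fit(gauss, r[sel], img[:, 32][sel],
                                     p0=[400.0, 25.0, 1.0])
        fwhm_um = abs(popt[2]) * 2.3548 * optics.pixel_size
        assert fwhm_um == pytest.approx(0.4, rel=1e-3)

    def test_polarization_rotation_equals_image_rotation(self, geometry):
        a = np.ones(360)
        img0 = render_frame(geometry, a, OpticsConfig(polarization_angle=0.0),
                            noise=False)
        img90 = render_frame(geometry, a, OpticsConfig(polarization_angle=90.0),
                             noise=False)
        assert np.allclose(np.rot90(img0), img90, atol=1e-9)

    def test_ring_must_fit(self, optics):
        geo = GUVGeometry(center=(31.5, 31.5), radius_um=14.0,
                          band_halfwidth_um=0.8, pixel_size_um=0.4)
        with pytest.raises(GeometryError):
            render_frame(geo, np.ones(360), optics, shape=(64, 64))

    def test_noise_variance_matches_poisson_plus_gaussian(self):
        """Single-pixel variance over 1e4 draws matches gain*signal + read^2."""
        optics = OpticsConfig(em_gain=3.0)
        geo = default_geometry(optics=optics)
        signal = render_frame(geo, np.ones(360), optics,
                              noise=False) - optics.background_level
        iy, ix = int(round(geo.center[1] - geo.radius_px)), 31
        s = signal[iy, ix]
        rng = substream(11, "variance-check")
        n = 10_000
        counts = (optics.em_gain * rng.poisson(s / optics.em_gain, size=n)
                  + rng.normal(0.0, optics.read_noise_sd, size=n))
        model = optics.em_gain * s + optics.read_noise_sd**2
        assert counts.var(ddof=1) == pytest.approx(model, rel=0.10)


class TestGenerateMovie:
    def test_determinism_bit_identical(self, optics, geometry):
        sched = default_schedule(5, 60.0)
        m1 = generate_movie(PRESETS["DOPC:DOPA"], geometry, optics, sched, seed=9)
        m2 = generate_movie(PRESETS["DOPC:DOPA"], geometry, optics, sched, seed=9)
        assert np.array_equal(m1.frames, m2.frames)
        m3 = generate_movie(PRESETS["DOPC:DOPA"], geometry, optics, sched, seed=10)
        assert not np.array_equal(m1.frames, m3.frames)

    def test_flat_composition_keeps_initial_intensity(self, optics, geometry):
        movie = generate_movie(PRESETS["SLPC:SLPA"], geometry, optics,
                               default_schedule(30, 60.0), seed=12)
        bg = optics.background_level
        ring = [(f - bg).sum() for f in movie.frames]
        rel = abs(ring[-1] / ring[0] - 1.0)
        # within noise: flicker (2%) dominates the integrated intensity scatter
        assert rel < 4.0 * optics.flicker_rel_sd

    def test_dopc_envelope_decays_below_tenth(self, optics, geometry):
        """Noise-free integrated intensity decreases monotonically and ends
        below 10% of its initial value by t = 1800 s."""
        sched = np.arange(0.0, 1801.0, 60.0)
        movie = generate_movie(PRESETS["DOPC:DOPA"], geometry, optics, sched,
                               seed=3, noise=False)
        ring = np.array([(f - optics.background_level).sum()
                         for f in movie.frames])
        assert np.all(np.diff(ring) < 0)
        assert ring[-1] / ring[0] < 0.1

    def test_schedule_validation(self, optics, geometry):
        with pytest.raises(InvalidParameterError):
            generate_movie(PRESETS["DOPC:DOPA"], geometry, optics, [], seed=0)
        with pytest.raises(InvalidParameterError):
            generate_movie(PRESETS["DOPC:DOPA"], geometry, optics,
                           [0.0, 60.0, 60.0], seed=0)
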