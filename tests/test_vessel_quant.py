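"""Profile metrology: centerline sampling, FWHM, HbT, trajectories."""

import numpy as np
import pandas as pd
import pytest

from vasodyn.geometry import Segment, VesselNetwork
from vasodyn.movie_io import Movie
from vasodyn.synthgen import GroundTruth, RenderConfig, render_movie, simulate_dilation
from vasodyn.vessel_quant import (IntensityProfile, SegmentSample,
                                  denoise_profile, denoise_profiles_batch,
                                  extract_profile, measure_profiles_batch,
                                  measure_segment, sample_centerline,
                                  twophoton_diameter, widefield_trajectories)

FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


class TestSampleCenterline:
    def test_straight_polyline_regular_samples(self):
        poly = np.array([[0.0, 0.0], [100.0, 0.0]])
        samples = sample_centerline(poly, spacing=20.0)
        assert len(samples) == 6
        np.testing.assert_allclose([s.arc for s in samples],
                                   [0, 20, 40, 60, 80, 100])
        for s in samples:
            np.testing.assert_allclose(s.tangent, [1.0, 0.0], atol=1e-9)

    def test_45um_spacing_on_450um_artery(self):
        poly = np.array([[0.0, 0.0], [450.0, 0.0]])
        samples = sample_centerline(poly, spacing=45.0)
        assert len(samples) == 11

    def test_corner_rotates_tangent(self):
        poly = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 100.0]])
        samples = sample_centerline(poly, spacing=20.0)
        first, last = samples[0], samples[-1]
        np.testing.assert_allclose(first.tangent, [1.0, 0.0], atol=1e-9)
        np.testing.assert_allclose(last.tangent, [0.0, 1.0], atol=1e-9)
        # finite-difference oracle at the corner: tangent bisects the turn
        corner = min(samples, key=lambda s: abs(s.arc - 100.0))
        assert corner.tangent[0] > 0 and corner.tangent[1] > 0

    def test_degenerate_polyline_rejected(self):
        with pytest.raises(ValueError):
            sample_centerline(np.array([[1.0, 1.0], [1.0, 1.0]]))


def _gaussian_vessel_frame(sigma_um, pixel_size, shape=(120, 120), depth=100.0,
                           background=0.0, axis="x"):
    h, w = shape
    ys = (np.arange(h) + 0.5) * pixel_size
    xs = (np.arange(w) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    c = h * pixel_size / 2.0
    perp = gy - c if axis == "x" else gx - c
    return background - depth * np.exp(-perp ** 2 / (2.0 * sigma_um ** 2))


class TestExtractProfile:
    def test_uniform_frame_gives_constant_profile(self):
        frame = np.full((100, 100), 7.0)
        s = SegmentSample(position=(50.0, 50.0), tangent=(1.0, 0.0), arc=0.0)
        prof = extract_profile(frame, s, pixel_size=1.0)
        assert prof.valid
        np.testing.assert_allclose(prof.values, -7.0, atol=1e-9)

    def test_gaussian_vessel_profile_preserves_sd(self):
        """Analytic oracle: parallel smoothing of a translation-invariant
        vessel leaves the perpendicular Gaussian (sd 6 µm) untouched."""
        frame = _gaussian_vessel_frame(6.0, pixel_size=0.5, shape=(240, 240))
        s = SegmentSample(position=(60.0, 60.0), tangent=(1.0, 0.0), arc=0.0)
        prof = extract_profile(frame, s, pixel_size=0.5)
        u = np.linspace(-35, 35, 200)
        peak = prof.values.max()
        base = prof.values.min()
        model = base + (peak - base) * np.exp(-u ** 2 / (2 * 6.0 ** 2))
        np.testing.assert_allclose(prof.values, model, atol=0.01 * (peak - base))

    def test_chord_leaving_frame_flags_invalid(self):
        frame = np.zeros((40, 40))
        s = SegmentSample(position=(2.0, 2.0), tangent=(1.0, 0.0), arc=0.0)
        prof = extract_profile(frame, s, pixel_size=1.0)
        assert not prof.valid

    def test_parallel_smoothing_attenuates_along_course_modulation(self):
        """Fourier oracle: a sinusoidal modulation along the vessel is
        attenuated by the Gaussian transfer function exp(-(2 pi f sigma)^2/2)."""
        pixel = 0.5
        shape = (240, 480)
        ys = (np.arange(shape[0]) + 0.5) * pixel
        xs = (np.arange(shape[1]) + 0.5) * pixel
        gx, gy = np.meshgrid(xs, ys)
        wavelength = 20.0
        frame = -(1.0 + 0.5 * np.sin(2 * np.pi * gx / wavelength)) * \
            np.exp(-(gy - 60.0) ** 2 / (2 * 8.0 ** 2))
        s = SegmentSample(position=(120.0, 60.0), tangent=(1.0, 0.0), arc=0.0)
        prof = extract_profile(frame, s, pixel_size=pixel)
        peak = prof.values.max()
        expected_atten = np.exp(-0.5 * (2 * np.pi * 5.6 / wavelength) ** 2)
        # the peak reflects 1 + 0.5*atten*sin(phase at center)
        phase = np.sin(2 * np.pi * 120.0 / wavelength)
        expected_peak = 1.0 + 0.5 * expected_atten * phase
        assert peak == pytest.approx(expected_peak, abs=0.03)


class TestDenoise:
    def test_noiseless_profile_unchanged(self):
        u = np.linspace(-35, 35, 200)
        vals = np.exp(-u ** 2 / (2 * 64.0))
        out = denoise_profile(IntensityProfile(values=vals))
        # unchanged to within the (tiny) universal threshold of the smooth
        # profile's own detail coefficients
        np.testing.assert_allclose(out.values, vals, atol=1e-4)

    def test_tophat_fwhm_preserved_under_noise(self, rng):
        u = np.linspace(-35, 35, 200)
        dx = 70 / 199
        tophat = np.where(np.abs(u) <= 12.0, 1.0, 0.0)
        noisy = tophat + rng.normal(0, 0.05, 200)
        den = denoise_profile(IntensityProfile(values=noisy))
        w, _ = measure_segment(den)
        assert abs(w - 24.0) <= 1.5 * dx

    def test_white_noise_variance_shrinks(self, rng):
        noise = rng.normal(0, 1.0, 200)
        den = denoise_profile(IntensityProfile(values=noise))
        assert den.values.var() < noise.var()

    def test_batch_matches_scalar(self, rng):
        profs = rng.normal(0, 1, (20, 200)) + \
            5 * np.exp(-np.linspace(-35, 35, 200) ** 2 / 128.0)
        batch = denoise_profiles_batch(profs)
        for i in range(20):
            single = denoise_profile(IntensityProfile(values=profs[i])).values
            np.testing.assert_allclose(batch[i], single, atol=1e-10)


class TestMeasureSegment:
    def test_gaussian_fwhm_analytic(self):
        u = np.linspace(-35, 35, 200)
        sigma = 8.5
        prof = IntensityProfile(values=np.exp(-u ** 2 / (2 * sigma ** 2)))
        w, _ = measure_segment(prof)
        assert w == pytest.approx(FWHM * sigma, rel=1e-3)
        assert FWHM * sigma == pytest.approx(20.02, abs=0.01)

    def test_offset_invariance(self):
        u = np.linspace(-35, 35, 200)
        vals = np.exp(-u ** 2 / (2 * 8.5 ** 2))
        w0, h0 = measure_segment(IntensityProfile(values=vals))
        w1, h1 = measure_segment(IntensityProfile(values=vals + 3.7))
        assert w1 == pytest.approx(w0, rel=1e-9)
        assert h1 == pytest.approx(h0, rel=1e-9)

    def test_tophat_width_and_hbt_summation_oracle(self):
        u = np.linspace(-35, 35, 200)
        dx = 70 / 199
        h = 2.5
        vals = np.where(np.abs(u) <= 12.0, h, 0.0)
        w, hbt = measure_segment(IntensityProfile(values=vals))
        n_in = int(np.sum(np.abs(u) <= 12.0))
        assert w == pytest.approx(24.0, abs=2 * dx)
        # direct summation oracle: h x (number of in-window points), up to
        # one sample of edge treatment
        assert hbt == pytest.approx(h * n_in, abs=2 * h)

    def test_flat_profile_flagged(self):
        w, hbt = measure_segment(IntensityProfile(values=np.zeros(200)))
        assert np.isnan(w) and np.isnan(hbt)

    def test_batch_matches_scalar_on_random_profiles(self, rng):
        u = np.linspace(-35, 35, 200)
        profs = np.stack([
            rng.uniform(0.5, 3) * np.exp(-(u - rng.uniform(-5, 5)) ** 2
                                         / (2 * rng.uniform(5, 12) ** 2))
            + rng.normal(0, 0.02, 200)
            for _ in range(50)])
        wb, hb = measure_profiles_batch(profs, 70 / 199)
        for i in range(50):
            ws, hs = measure_segment(IntensityProfile(values=profs[i]))
            if np.isnan(ws):
                assert np.isnan(wb[i])
            else:
                assert wb[i] == pytest.approx(ws, abs=1e-9)
                assert hb[i] == pytest.approx(hs, abs=1e-9)


def _static_trial_movie(n_trials=3, n_frames=12, onset=6, noise=None):
    frame = _gaussian_vessel_frame(10.0, pixel_size=2.0, shape=(100, 100),
                                   depth=100.0, background=1000.0)
    frames = np.tile(frame, (n_trials * n_frames, 1, 1))
    if noise is not None:
        frames = frames + noise
    movie = Movie(frames=frames, channel="ios", frame_period=0.14, pixel_size=2.0)
    trials = pd.DataFrame({
        "trial": np.arange(n_trials),
        "start_frame": np.arange(n_trials) * n_frames,
        "onset_frame": np.arange(n_trials) * n_frames + onset,
        "n_frames": n_frames,
    })
    poly = np.array([[40.0, 100.0], [160.0, 100.0]])
    net = VesselNetwork(segments=[Segment(points=poly, d0=23.5)],
                        source=(40.0, 100.0), field_size=(200.0, 200.0))
    return movie, net, trials


class TestWidefieldTrajectories:
    def test_static_movie_gives_zero_trajectories(self):
        movie, net, trials = _static_trial_movie()
        bg = Movie(frames=np.zeros((1, 100, 100)), channel="ios",
                   frame_period=0.14, pixel_size=2.0)
        wt = widefield_trajectories(movie, net, trials, background=bg)
        assert np.nanmax(np.abs(wt.frac_width)) < 1e-9
        assert np.nanmax(np.abs(wt.frac_hbt)) < 1e-9

    def test_identical_trials_give_identical_trajectories(self):
        movie, net, trials = _static_trial_movie()
        bg = Movie(frames=np.zeros((1, 100, 100)), channel="ios",
                   frame_period=0.14, pixel_size=2.0)
        wt = widefield_trajectories(movie, net, trials, background=bg)
        np.testing.assert_array_equal(wt.frac_hbt[0], wt.frac_hbt[1])
        np.testing.assert_array_equal(wt.frac_hbt[0], wt.frac_hbt[2])

    def test_missing_background_warns(self):
        movie, net, trials = _static_trial_movie()
        with pytest.warns(UserWarning, match="background"):
            widefield_trajectories(movie, net, trials, background=None)

    def test_rejects_gcamp_channel(self):
        movie, net, trials = _static_trial_movie()
        movie = Movie(frames=movie.frames, channel="gcamp",
                      frame_period=0.14, pixel_size=2.0)
        with pytest.raises(ValueError):
            widefield_trajectories(movie, net, trials)


class TestRenderedMetrology:
    def test_fwhm_of_rendered_gaussian_vessel(self, straight_network):
        """The rendered cross-section FWHM equals the true diameter within
        1% at fine pixel sampling."""
        truth = GroundTruth(a0=0.0, noise_sd=0.0)
        field = simulate_dilation(straight_network, truth, np.array([0.0]))
        cfg = RenderConfig(pixel_size=2.0, photon_scale=0.0)
        movie = render_movie(field, "ios", cfg)
        s = SegmentSample(position=(1000.0, 100.0), tangent=(1.0, 0.0), arc=0.0)
        prof = denoise_profile(extract_profile(movie.frames[0], s, pixel_size=2.0))
        w, _ = measure_segment(prof)
        assert w == pytest.approx(25.0, rel=0.01)

    def test_hbt_monotone_in_diameter(self):
        """Noiseless renders: HbT strictly increasing in true diameter
        across a 15-60 µm sweep at fixed absorbance gain."""
        cfg = RenderConfig(pixel_size=2.0, photon_scale=0.0)
        hbts = []
        for d0 in np.linspace(15.0, 60.0, 10):
            poly = np.column_stack([np.linspace(50, 2050, 41), np.full(41, 100.0)])
            net = VesselNetwork(segments=[Segment(points=poly, d0=float(d0))],
                                source=(50.0, 100.0), field_size=(2100.0, 200.0))
            field = simulate_dilation(net, GroundTruth(a0=0.0, noise_sd=0.0),
                                      np.array([0.0]))
            movie = render_movie(field, "ios", cfg)
            s = SegmentSample(position=(1000.0, 100.0), tangent=(1.0, 0.0), arc=0.0)
            prof = denoise_profile(extract_profile(movie.frames[0], s, pixel_size=2.0))
            _, hbt = measure_segment(prof)
            hbts.append(hbt)
        assert np.all(np.diff(hbts) > 0)

    def test_rotation_equivariance(self):
        """Rotating frame and centerline by 90 degrees changes width and
        HbT by <0.5%."""
        frame_x = _gaussian_vessel_frame(9.0, pixel_size=1.0, shape=(160, 160),
                                         depth=50.0, background=500.0, axis="x")
        frame_y = _gaussian_vessel_frame(9.0, pixel_size=1.0, shape=(160, 160),
                                         depth=50.0, background=500.0, axis="y")
        sx = SegmentSample(position=(80.0, 80.0), tangent=(1.0, 0.0), arc=0.0)
        sy = SegmentSample(position=(80.0, 80.0), tangent=(0.0, 1.0), arc=0.0)
        wx, hx = measure_segment(denoise_profile(extract_profile(frame_x, sx, 1.0)))
        wy, hy = measure_segment(denoise_profile(extract_profile(frame_y, sy, 1.0)))
        assert wy == pytest.approx(wx, rel=0.005)
        assert hy == pytest.approx(hx, rel=0.005)


def _cylinder_movie(d_um, n_frames, pixel=1.0, shape=(80, 200), step_frame=None,
                    d2_um=None):
    ys = (np.arange(shape[0]) + 0.5) * pixel
    xs = (np.arange(shape[1]) + 0.5) * pixel
    gx, gy = np.meshgrid(xs, ys)
    frames = []
    for k in range(n_frames):
        d = d_um if step_frame is None or k < step_frame else d2_um
        # anti-aliased edge: per-pixel coverage of the lumen
        cover = np.clip((d / 2.0 - np.abs(gy - 40.0)) / pixel + 0.5, 0.0, 1.0)
        frames.append(1000.0 * cover)
    return Movie(frames=np.stack(frames).astype(float), channel="ios",
                 frame_period=0.1, pixel_size=pixel)


class TestTwoPhoton:
    def test_constant_cylinder_diameter(self):
        movie = _cylinder_movie(25.0, n_frames=4)
        centerline = np.array([[30.0, 40.0], [170.0, 40.0]])
        traj = twophoton_diameter(movie, centerline)
        assert np.all(np.isfinite(traj.widths_um))
        np.testing.assert_allclose(traj.widths_um, 25.0, atol=0.5)

    def test_step_dilation_ratio(self):
        movie = _cylinder_movie(25.0, n_frames=8, step_frame=4, d2_um=30.0)
        centerline = np.array([[30.0, 40.0], [170.0, 40.0]])
        traj = twophoton_diameter(movie, centerline)
        ratio = traj.widths_um[6] / traj.widths_um[1]
        assert ratio == pytest.approx(30.0 / 25.0, abs=0.02)

    def test_branch_rung_flagged(self):
        """Peak-count oracle: a rung crossing two parallel vessels has two
        peaks above half-max and is excluded from the average."""
        pixel = 1.0
        shape = (100, 120)
        ys = (np.arange(shape[0]) + 0.5) * pixel
        xs = (np.arange(shape[1]) + 0.5) * pixel
        gx, gy = np.meshgrid(xs, ys)
        main = 1000.0 * (np.abs(gy - 50.0) <= 10.0)
        # a second vessel only under the right half of the field
        other = 1000.0 * ((np.abs(gy - 20.0) <= 8.0) & (gx > 80.0))
        movie = Movie(frames=(main + other)[None].astype(float), channel="ios",
                      frame_period=0.1, pixel_size=pixel)
        centerline = np.array([[20.0, 50.0], [110.0, 50.0]])
        traj = twophoton_diameter(movie, centerline, profile_length_um=80.0)
        assert traj.n_flagged[0] >= 1
        assert traj.widths_um[0] == pytest.approx(20.0, abs=1.0)
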