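"""Evoked-activity maps: correction, normalization, masks, kernel."""

import numpy as np
import pandas as pd
import pytest

from vasodyn.activity_map import (ActivityMap, distance_to_activity,
                                  evoked_map, hb_correct, local_activity,
                                  normalize_session)
from vasodyn.movie_io import Movie


class TestHbCorrect:
    def test_identity_when_ios_at_baseline(self, rng):
        g = rng.uniform(0, 10, (20, 20))
        base = rng.uniform(1, 2, (20, 20))
        out = hb_correct(g, base, base)
        np.testing.assert_allclose(out, g, atol=1e-12)

    def test_zero_gcamp_stays_zero(self):
        out = hb_correct(np.zeros((5, 5)), np.full((5, 5), 0.9), np.ones((5, 5)))
        np.testing.assert_array_equal(out, np.zeros((5, 5)))

    def test_nonpositive_baseline_marked_invalid(self):
        base = np.ones((4, 4))
        base[1, 2] = 0.0
        out = hb_correct(np.ones((4, 4)), np.ones((4, 4)), base)
        assert np.isnan(out[1, 2])
        assert np.isfinite(out).sum() == 15

    def test_crosstalk_correction_recovers_blob(self, straight_network):
        """Forward-model oracle: dividing by the fractional 530 nm
        reflectance undoes the rendered kappa crosstalk within 5%."""
        from vasodyn.synthgen import GroundTruth, RenderConfig, render_movie, simulate_dilation
        t = np.arange(0, 7, 0.14)
        truth = GroundTruth(a0=0.15, noise_sd=0.0, t0=1.0, d_rise=0.2, duration=3.0)
        field = simulate_dilation(straight_network, truth, t)
        stim = truth.envelope(t - truth.t0)
        cfg0 = RenderConfig(photon_scale=0.0, kappa=0.0)
        cfg1 = RenderConfig(photon_scale=0.0, kappa=0.8)
        g0 = render_movie(field, "gcamp", cfg0, stim_course=stim)
        g1 = render_movie(field, "gcamp", cfg1, stim_course=stim)
        ios = render_movie(field, "ios", cfg0)
        # crosstalk here multiplies gcamp by (1 - kappa*absorb_frac);
        # absorb_frac = 1 - ios/background
        base = np.full(ios.frames.shape[1:], cfg0.background)
        k = len(t) - 1
        absorb = 1.0 - ios.frames[k] / cfg0.background
        corrected = g1.frames[k] / (1.0 - 0.8 * absorb)
        np.testing.assert_allclose(corrected, g0.frames[k], rtol=0.05)


def _trial_movies(frames_list, frame_period=0.14, pixel_size=10.0):
    return [Movie(frames=np.asarray(f, dtype=float), channel="gcamp",
                  frame_period=frame_period, pixel_size=pixel_size)
            for f in frames_list]


class TestNormalizeSession:
    def test_constant_movie_degenerate_rescale(self):
        movies = _trial_movies([np.full((6, 16, 16), 5.0)])
        table = pd.DataFrame({"onset_frame": [3]})
        with pytest.warns(UserWarning, match="degenerate"):
            out = normalize_session(movies, table)
        np.testing.assert_allclose(out[0].frames, 0.5)

    def test_trial_permutation_invariance(self, rng):
        frames = [rng.uniform(1, 2, (6, 16, 16)) for _ in range(3)]
        table = pd.DataFrame({"onset_frame": [3, 3, 3]})
        a = normalize_session(_trial_movies(frames), table)
        b = normalize_session(_trial_movies(frames[::-1]), table)
        np.testing.assert_allclose(a[0].frames, b[2].frames)

    def test_blob_doubling_maps_to_unit_range(self):
        """Percentile oracle: a doubling blob lands near 1, background
        near 0 after the 15th/99th percentile rescale."""
        h = w = 40
        yy, xx = np.mgrid[:h, :w]
        blob = np.exp(-((yy - 20) ** 2 + (xx - 20) ** 2) / (2 * 9.0))
        pre = np.ones((4, h, w))
        post = 1.0 + 1.0 * blob     # doubling at the blob centre
        frames = np.concatenate([pre, np.tile(post, (4, 1, 1))])
        movies = _trial_movies([frames])
        table = pd.DataFrame({"onset_frame": [4]})
        out = normalize_session(movies, table, smooth_um=10.0)
        resp = out[0].frames[-1]
        assert resp[20, 20] > 0.9
        assert abs(resp[2, 2]) < 0.1


    def test_idempotent_without_smoothing_and_rescale(self, rng):
        """Re-normalizing an already-normalized session (smoothing off,
        rescale off) is a no-op: the per-pixel pre-stimulus baseline of
        normalized data is 1."""
        frames = [rng.uniform(1, 2, (6, 12, 12))]
        table = pd.DataFrame({"onset_frame": [3]})
        once = normalize_session(_trial_movies(frames), table,
                                 smooth_um=0.0, rescale=False, hot_pixel=False)
        twice = normalize_session(once, table, smooth_um=0.0, rescale=False,
                                  hot_pixel=False)
        np.testing.assert_allclose(twice[0].frames, once[0].frames, atol=1e-12)


class TestEvokedMap:
    def _movie_from_response(self, resp, onset=2, n_post=10):
        frames = np.concatenate([np.zeros((onset,) + resp.shape),
                                 np.tile(resp, (n_post, 1, 1))])
        return Movie(frames=frames, channel="gcamp", frame_period=0.14,
                     pixel_size=10.0)

    def test_disk_above_threshold_is_mask(self):
        yy, xx = np.mgrid[:30, :30]
        disk = ((yy - 15) ** 2 + (xx - 15) ** 2) <= 36
        resp = np.where(disk, 0.6, 0.1)
        mv = self._movie_from_response(resp)
        table = pd.DataFrame({"onset_frame": [2]})
        amap = evoked_map([mv], table)
        np.testing.assert_array_equal(amap.mask, disk)

    def test_exact_half_excluded_by_strict_threshold(self):
        resp = np.full((10, 10), 0.5)
        mv = self._movie_from_response(resp)
        amap = evoked_map([mv], pd.DataFrame({"onset_frame": [2]}))
        assert not amap.mask.any()

    def test_no_trials_raises(self):
        with pytest.raises(ValueError):
            evoked_map([], pd.DataFrame({"onset_frame": []}))

    def test_synthetic_blob_mask_area(self):
        """Truth-threshold oracle: mask area within 10% of the area where
        the true mean-window response exceeds 0.5."""
        yy, xx = np.mgrid[:50, :50]
        resp = np.exp(-((yy - 25) ** 2 + (xx - 25) ** 2) / (2 * 64.0))
        mv = self._movie_from_response(resp)
        amap = evoked_map([mv], pd.DataFrame({"onset_frame": [2]}))
        true_area = (resp > 0.5).sum()
        assert amap.mask.sum() == pytest.approx(true_area, rel=0.1)


class TestDistanceToActivity:
    def test_point_inside_mask_is_zero(self):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        assert distance_to_activity(mask, (75.0, 75.0), pixel_size=10.0) == 0.0

    def test_single_pixel_known_distance(self):
        mask = np.zeros((50, 50), bool)
        mask[10, 40] = True          # centre at (405, 105) µm
        d = distance_to_activity(mask, (105.0, 105.0), pixel_size=10.0)
        assert d == pytest.approx(300.0, abs=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            distance_to_activity(np.zeros((5, 5), bool), (10.0, 10.0), 10.0)

    def test_ring_mask_matches_exhaustive_scan(self, rng):
        """Exhaustive pixel-scan oracle on a ring mask and random masks."""
        yy, xx = np.mgrid[:40, :40]
        r = np.sqrt((yy - 20) ** 2 + (xx - 20) ** 2)
        ring = (r > 10) & (r < 12)
        masks = [ring] + [rng.random((40, 40)) > 0.95 for _ in range(3)]
        for mask in masks:
            if not mask.any():
                continue
            point = (rng.uniform(0, 400), rng.uniform(0, 400))
            d = distance_to_activity(mask, point, pixel_size=10.0)
            rr, cc = np.nonzero(mask)
            brute = min(np.hypot((c + 0.5) * 10 - point[0], (r2 + 0.5) * 10 - point[1])
                        for r2, c in zip(rr, cc))
            if d > 0:
                assert d == pytest.approx(brute, abs=1e-9)
            else:
                # inside an activated pixel: oracle distance below one
                # pixel diagonal
                assert brute < 10 * np.sqrt(2)


class TestLocalActivity:
    def test_single_pixel_at_zero_distance(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        l = local_activity(mask, (25.0, 25.0), pixel_size=10.0, sigma_um=400.0)
        assert l == pytest.approx(1.0, abs=1e-12)

    def test_single_pixel_at_sigma(self):
        mask = np.zeros((3, 200), bool)
        mask[1, 0] = True
        # pixel centre at x = 5 µm; position 405 µm away
        l = local_activity(mask, (405.0, 15.0), pixel_size=10.0, sigma_um=400.0)
        assert l == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_patch_matches_bruteforce_sum(self, rng):
        """Brute-force summation oracle on a 10x10 patch and random masks."""
        for trial in range(3):
            mask = np.zeros((30, 30), bool)
            if trial == 0:
                mask[10:20, 10:20] = True
            else:
                mask = rng.random((30, 30)) > 0.8
            pos = (rng.uniform(0, 300), rng.uniform(0, 300))
            l = local_activity(mask, pos, pixel_size=10.0, sigma_um=400.0)
            brute = 0.0
            for r in range(30):
                for c in range(30):
                    if mask[r, c]:
                        D = np.hypot((c + 0.5) * 10 - pos[0], (r + 0.5) * 10 - pos[1])
                        brute += np.exp(-D ** 4 / (2 * 400.0 ** 4))
            assert l == pytest.approx(brute, rel=1e-9)

    def test_additive_over_disjoint_masks(self):
        a = np.zeros((20, 20), bool); a[3, 4] = True
        b = np.zeros((20, 20), bool); b[15, 16] = True
        pos = (100.0, 100.0)
        assert local_activity(a | b, pos, 10.0) == pytest.approx(
            local_activity(a, pos, 10.0) + local_activity(b, pos, 10.0), rel=1e-12)
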