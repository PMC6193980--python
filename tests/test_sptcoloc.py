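"""Two-colour SPT: registration, smoothing, linking, colocalisation, null."""

import numpy as np
import pytest

from oligoscope import (
    Track,
    TrackSet,
    coincidental_fraction,
    detect_coloc,
    fit_registration,
    ks_two_tailed,
    link_features,
    randomize_tracks,
    simulate_tracks,
    smooth_track,
)


def make_track(xy, tid=0, channel="A", start=0):
    xy = np.atleast_2d(np.asarray(xy, float))
    return Track(tid, channel, np.arange(start, start + len(xy)), xy)


class TestRegistration:
    def test_identity_map_zero_residual(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (30, 2))
        model = fit_registration(pts, pts)
        assert model.residual_rms_px == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(model.apply(pts), pts, atol=1e-9)

    def test_affine_map_recovered_exactly(self):
        rng = np.random.default_rng(1)
        b = rng.uniform(0, 100, (40, 2))
        M = np.array([[1.01, 0.02], [-0.015, 0.99]])
        t = np.array([3.0, -2.0])
        a = b @ M.T + t
        model = fit_registration(a, b)
        assert model.residual_rms_px < 1e-9
        np.testing.assert_allclose(model.apply(b), a, atol=1e-6)

    def test_cubic_warp_with_noise(self):
        rng = np.random.default_rng(2)
        b = rng.uniform(0, 50, (200, 2))
        x, y = b[:, 0], b[:, 1]
        a = np.column_stack([
            x + 1e-5 * x**3 + 2e-5 * x * y**2 + 0.5,
            y - 1e-5 * y**3 + 1e-5 * x**2 * y - 0.3,
        ]) + rng.normal(0, 0.05, b.shape)
        model = fit_registration(a, b)
        assert model.residual_rms_px <= 0.1

    def test_insufficient_pairs_rejected(self):
        pts = np.random.default_rng(3).uniform(0, 10, (5, 2))
        with pytest.raises(ValueError):
            fit_registration(pts, pts)


class TestSmoothing:
    def test_constant_track_unchanged(self):
        t = make_track(np.tile([5.0, 7.0], (20, 1)))
        sm = smooth_track(t)
        np.testing.assert_allclose(sm.xy, t.xy, atol=1e-12)

    def test_single_point_unchanged(self):
        t = make_track([[1.0, 2.0]])
        sm = smooth_track(t)
        np.testing.assert_allclose(sm.xy, t.xy)

    def test_white_noise_variance_reduction(self):
        # linear filter: output variance = input variance * sum(k_norm^2)
        rng = np.random.default_rng(4)
        n = 20000
        t = make_track(rng.normal(0, 1.0, (n, 2)))
        sm = smooth_track(t, fwhm_frames=4.0)
        sigma = 4.0 / (2 * np.sqrt(2 * np.log(2)))
        half = int(np.ceil(4 * sigma))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
        k /= k.sum()
        expected = (k**2).sum()
        interior = slice(half, n - half)
        ratio = sm.xy[interior, 0].var() / t.xy[interior, 0].var()
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_frame_indices_unchanged(self):
        t = make_track(np.random.default_rng(5).normal(size=(9, 2)), start=11)
        sm = smooth_track(t)
        np.testing.assert_array_equal(sm.frames, t.frames)


class TestLinking:
    def test_single_slow_particle_one_track(self):
        dets = {f: np.array([[10 + 0.1 * f, 20.0]]) for f in range(15)}
        ts = link_features(dets, max_step_px=2.0)
        assert len(ts) == 1
        assert len(ts.tracks[0]) == 15

    def test_distant_particles_never_merged(self):
        dets = {
            f: np.array([[10.0 + 0.05 * f, 10.0], [60.0 - 0.05 * f, 60.0]])
            for f in range(10)
        }
        ts = link_features(dets, max_step_px=2.0)
        assert len(ts) == 2
        assert all(len(t) == 10 for t in ts.tracks)

    def test_brownian_links_mostly_correct(self):
        rng = np.random.default_rng(6)
        n_particles, n_frames, step = 12, 40, 0.3
        paths = np.cumsum(
            rng.normal(0, step, (n_frames, n_particles, 2)), axis=0
        ) + rng.uniform(10, 90, (1, n_particles, 2))
        dets = {f: paths[f] for f in range(n_frames)}
        ts = link_features(dets, max_step_px=2.0)
        # greedy mutual-NN should keep the low-density particles whole
        long_tracks = [t for t in ts.tracks if len(t) == n_frames]
        assert len(long_tracks) >= int(0.95 * n_particles)


class TestDetectColoc:
    def test_identical_tracks_one_event(self):
        xy = np.cumsum(np.ones((10, 2)) * 0.1, axis=0) + 5
        a = TrackSet([make_track(xy, 0, "A")], (50, 50))
        b = TrackSet([make_track(xy.copy(), 1, "B")], (50, 50))
        s = detect_coloc(a, b)
        assert s.raw_fraction_a == 1.0 and s.raw_fraction_b == 1.0
        assert len(s.events) == 1
        assert s.events[0].tau_on_s == pytest.approx(0.5)

    def test_distant_tracks_no_events(self):
        a = TrackSet([make_track(np.tile([5.0, 5.0], (10, 1)))], (50, 50))
        b = TrackSet([make_track(np.tile([8.0, 5.0], (10, 1)))], (50, 50))
        s = detect_coloc(a, b)
        assert s.raw_fraction_a == 0.0
        assert not s.events

    def test_four_close_frames_below_threshold(self):
        xy_a = np.tile([5.0, 5.0], (10, 1))
        xy_b = np.tile([9.0, 5.0], (10, 1))
        xy_b[3:7] = [5.2, 5.0]  # exactly 4 close frames
        a = TrackSet([make_track(xy_a)], (50, 50))
        b = TrackSet([make_track(xy_b)], (50, 50))
        s = detect_coloc(a, b, min_total_frames=5)
        assert s.raw_fraction_a == 0.0

    def test_five_close_frames_meets_threshold(self):
        xy_a = np.tile([5.0, 5.0], (10, 1))
        xy_b = np.tile([9.0, 5.0], (10, 1))
        xy_b[3:8] = [5.2, 5.0]
        a = TrackSet([make_track(xy_a)], (50, 50))
        b = TrackSet([make_track(xy_b)], (50, 50))
        s = detect_coloc(a, b, min_total_frames=5)
        assert s.raw_fraction_a == 1.0
        assert len(s.events) == 1

    def test_distance_rule_is_strict(self):
        xy_a = np.tile([5.0, 5.0], (10, 1))
        xy_b = np.tile([6.0, 5.0], (10, 1))  # exactly 1 px apart
        s = detect_coloc(
            TrackSet([make_track(xy_a)], (50, 50)),
            TrackSet([make_track(xy_b)], (50, 50)),
        )
        assert s.raw_fraction_a == 0.0

    def test_empty_sets_explicit_empty_result(self):
        s = detect_coloc(TrackSet([], (50, 50)), TrackSet([], (50, 50)))
        assert s.raw_fraction_a == 0.0 and not s.events


class TestRandomisation:
    def test_step_length_multiset_preserved(self):
        rng = np.random.default_rng(7)
        xy = np.cumsum(rng.normal(0, 0.5, (30, 2)), axis=0) + 50
        ts = TrackSet([make_track(xy)], (100, 100))
        rand = randomize_tracks(ts, seed=8)
        # wrap can only break steps at the boundary; with a centred track the
        # isometry preserves every step length
        steps_in = np.hypot(*np.diff(xy, axis=0).T)
        steps_out = np.hypot(*np.diff(rand.tracks[0].xy, axis=0).T)
        wrap_free = np.abs(np.diff(rand.tracks[0].xy, axis=0)).max(axis=1) < 50
        np.testing.assert_allclose(
            np.sort(steps_out[wrap_free]), np.sort(steps_in[wrap_free]), rtol=1e-9
        )

    def test_track_count_and_durations_preserved(self):
        rng = np.random.default_rng(9)
        tracks = [
            make_track(rng.uniform(0, 100, (rng.integers(5, 20), 2)), tid=i)
            for i in range(10)
        ]
        ts = TrackSet(tracks, (100, 100))
        rand = randomize_tracks(ts, seed=10)
        assert len(rand) == 10
        in_lens = sorted(len(t) for t in tracks)
        out_lens = sorted(len(t) for t in rand.tracks)
        # drawn with replacement: durations come from the measured multiset
        assert set(out_lens) <= set(in_lens)

    def test_single_point_tracks_scatter_uniformly(self):
        ts = TrackSet([make_track([[50.0, 50.0]], tid=i) for i in range(2000)], (100, 100))
        rand = randomize_tracks(ts, seed=11)
        pos = np.vstack([t.xy for t in rand.tracks])
        assert abs(pos[:, 0].mean() - 50) < 2
        assert abs(pos[:, 0].var() - 100**2 / 12) < 150

    def test_flip_rate_is_half(self):
        # rotations preserve handedness, the x-flip inverts it, so the sign
        # of the cross product of the two steps of an L-shaped track reads
        # out the flip directly
        n = 10000
        rng = np.random.default_rng(12)
        xy3 = np.array([[0, 0], [1, 0], [1, 0.5]]) + 50.0
        ts3 = TrackSet([make_track(xy3)], (100, 100))
        flips = 0
        for _ in range(n):
            r = randomize_tracks(ts3, seed=int(rng.integers(2**31)))
            s = np.diff(r.tracks[0].xy, axis=0)
            s = np.where(np.abs(s) > 50, s - np.sign(s) * 100, s)
            cross = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
            if cross < 0:  # original cross is positive
                flips += 1
        assert flips / n == pytest.approx(0.5, abs=0.015)


class TestCoincidence:
    def test_empty_channel_gives_zero(self):
        a, b, _ = simulate_tracks(5, 0, seed=13, n_frames=20)
        empty = TrackSet([], b.fov_px)
        ca, cb = coincidental_fraction(a, empty, n_rand=3, seed=0)
        assert ca == 0.0 and cb == 0.0

    def test_independent_channels_corrected_near_zero(self):
        a, b, _ = simulate_tracks(150, 0, seed=14, n_frames=60)
        raw = detect_coloc(a, b)
        ca, cb = coincidental_fraction(a, b, n_rand=20, seed=1)
        corrected = 0.5 * (raw.raw_fraction_a - ca + raw.raw_fraction_b - cb)
        # SE of the raw fraction estimate at n tracks
        se = np.sqrt(max(raw.raw_fraction, 1.0 / 150) / 150)
        assert abs(corrected) <= 2 * se + 0.02


class TestTauOnRecovery:
    def test_event_durations_match_generator_mean(self):
        # exponential bound intervals of mean 1 s; detected event durations
        # should recover the mean within 10% once frame quantisation is
        # negligible relative to the interval length
        a, b, truth = simulate_tracks(0, 250, tau_on_mean_s=1.0, seed=11, n_frames=200)
        sa = TrackSet([smooth_track(t) for t in a.tracks], a.fov_px)
        sb = TrackSet([smooth_track(t) for t in b.tracks], b.fov_px)
        s = detect_coloc(sa, sb)
        assert s.tau_on.size >= 500
        assert abs(s.tau_on.mean() - 1.0) / 1.0 <= 0.10


class TestKs:
    def test_identical_samples(self):
        x = np.linspace(0, 1, 50)
        d, p = ks_two_tailed(x, x)
        assert d == 0.0
        assert p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = ks_two_tailed([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert d == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_tailed([], [1.0])
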