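"""Detector, sub-pixel localizer, nearest-neighbor linker, and track scoring."""

import math
from dataclasses import replace

import numpy as np
import pytest

from spotjump import (
    Detection,
    ImagingModel,
    PopulationMix,
    SimulationConfig,
    TrackingParams,
    bandpass,
    detect_spots,
    detect_stack,
    estimate_precision,
    link_nearest_neighbor,
    localize_subpixel,
    render_stack,
    score_tracks,
    simulate_trajectories,
    track_stack,
)
from spotjump.detect_track import noise_sd_mad

from conftest import make_grid_stack


def render_spot(offset_rc=(0.0, 0.0), amplitude=100.0, shape=(25, 25)):
    """Noise-free single PSF at the frame center plus a sub-pixel offset.

    Supersampling 40 keeps the delta-placement quantization (0.5/k px) well
    below the localization tolerances under test.
    """
    model = ImagingModel(
        frame_shape=shape, background=0.0, read_noise_sd=0.0, amplitude=amplitude,
        supersampling=40,
    )
    from spotjump.simulate import GroundTruthTrajectory

    px = model.pixel_size_um
    cy, cx = shape[0] // 2, shape[1] // 2
    traj = GroundTruthTrajectory(
        0, np.arange(2),
        x=np.full(2, (cx + offset_rc[1]) * px), y=np.full(2, (cy + offset_rc[0]) * px),
        population_label=np.zeros(2, dtype=int),
    )
    return render_stack([traj], model, add_noise=False, n_frames=1)[0], (cy, cx), model


class TestBandpass:
    def test_constant_frame_maps_to_zero(self):
        out = bandpass(np.full((32, 32), 7.5), 1.0, 3.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_invalid_cuts(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((16, 16)), 3.0, 1.0)
        with pytest.raises(ValueError):
            bandpass(np.zeros((16, 16)), 1.0, 20.0)

    def test_peak_position_preserved(self):
        frame, (cy, cx), _ = render_spot()
        out = bandpass(frame, 1.0, 3.0)
        assert np.unravel_index(np.argmax(out), out.shape) == (cy, cx)

    def test_contrast_improves_on_noisy_frame(self, imaging_snr6, rng):
        stack, trajs, model = make_grid_stack(imaging_snr6, 1, 5, 0.0, 1.5, seed=9)
        frame = stack[0]
        i = int(round(trajs[0].y[0] / model.pixel_size_um))
        j = int(round(trajs[0].x[0] / model.pixel_size_um))
        bp = bandpass(frame, 1.0, 3.0, clip=False)
        raw_contrast = (frame[i, j] - np.median(frame)) / noise_sd_mad(frame)
        bp_contrast = bp[i, j] / noise_sd_mad(bp)
        assert bp_contrast > raw_contrast


class TestDetectSpots:
    def test_noise_only_false_positives_below_one_per_frame(self, imaging_snr6, rng):
        model = replace(imaging_snr6, frame_shape=(150, 150))
        stack = render_stack([], model, rng=rng, n_frames=20)
        params = TrackingParams.for_imaging(model)
        dets = detect_stack(stack, params)
        assert np.mean([len(d) for d in dets]) < 1.0

    def test_isolated_particle_detected_within_one_pixel(self, isolated_stack_snr6):
        stack, trajs, model = isolated_stack_snr6
        params = TrackingParams.for_imaging(model)
        dets = detect_stack(stack, params)
        px = model.pixel_size_um
        n_extra = 0
        for f, d_list in enumerate(dets):
            hits = [
                d for d in d_list
                if abs(d.x_um - trajs[0].x[f]) < px and abs(d.y_um - trajs[0].y[f]) < px
            ]
            assert len(hits) == 1  # the particle is always found, exactly once
            n_extra += len(d_list) - len(hits)
        assert n_extra <= 0.1 * len(dets)  # stray noise peaks stay rare

    def test_unresolvable_pair_gives_single_detection(self):
        # two particles one pixel apart: overlapping PSFs cannot be resolved
        frame1, (cy, cx), model = render_spot((0.0, 0.0))
        frame2, _, _ = render_spot((0.0, 1.0))
        frame = frame1 + frame2
        dets = detect_spots(
            bandpass(frame, 1.0, 3.0), threshold=1.0, min_separation=1.5,
            psf_sigma_px=model.psf_sigma_px, pixel_size_um=model.pixel_size_um,
        )
        assert len(dets) == 1


class TestLocalizeSubpixel:
    def test_centered_spot_zero_offset(self):
        frame, (cy, cx), model = render_spot((0.0, 0.0))
        r, c, ok = localize_subpixel(frame, (cy, cx), model.psf_sigma_px)
        assert ok
        assert r == pytest.approx(cy, abs=0.02) and c == pytest.approx(cx, abs=0.02)

    @pytest.mark.parametrize("dy,dx", [(0.3, 0.0), (0.0, 0.3), (-0.3, 0.2)])
    def test_offset_recovered(self, dy, dx):
        frame, (cy, cx), model = render_spot((dy, dx))
        r, c, ok = localize_subpixel(frame, (cy, cx), model.psf_sigma_px)
        assert ok
        assert r - cy == pytest.approx(dy, abs=0.05)
        assert c - cx == pytest.approx(dx, abs=0.05)

    def test_flat_window_falls_back_flagged(self):
        r, c, ok = localize_subpixel(np.zeros((15, 15)), (7, 7), 1.5)
        assert not ok
        assert (r, c) == (7.0, 7.0)


class TestPrecision:
    def test_noise_free_immobile_sigma_zero(self):
        model = ImagingModel(frame_shape=(48, 48), background=0.0, read_noise_sd=0.0, amplitude=100.0)
        cfg = SimulationConfig(
            mix=PopulationMix.single(0.0), imaging=model, n_particles=4, n_frames=12,
            initial_min_spacing_um=1.2,
        )
        trajs = simulate_trajectories(cfg)
        stack = render_stack(trajs, model, add_noise=False, n_frames=12)
        params = TrackingParams.for_imaging(model, max_disp_um=0.2)
        est = estimate_precision(stack, params)
        assert est.sigma_nm < 1.0

    def test_sigma_decreases_with_snr(self):
        from spotjump import measure_localization_sigma

        sigmas = [measure_localization_sigma(snr, seed=2) for snr in (3.5, 6.0, 14.0)]
        assert sigmas[0] > sigmas[1] > sigmas[2]
        # plausible single-molecule range at a 106-nm pixel
        assert all(0.002 < s < 0.06 for s in sigmas)

    def test_too_few_frames_raises(self):
        params = TrackingParams()
        with pytest.raises(ValueError):
            estimate_precision(np.zeros((5, 32, 32)), params)


def tracks_from_positions(positions_by_frame, max_disp):
    dets = [
        [Detection(frame=f, x_um=x, y_um=y, intensity=1.0) for x, y in pts]
        for f, pts in enumerate(positions_by_frame)
    ]
    return link_nearest_neighbor(dets, max_disp)


class TestLinking:
    def test_single_particle_full_track(self):
        pts = [[(0.1 * f, 0.05 * f)] for f in range(10)]
        tracks = tracks_from_positions(pts, max_disp=0.5)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10
        np.testing.assert_array_equal(tracks[0].frames, np.arange(10))

    def test_tiny_max_disp_gives_singletons(self):
        pts = [[(0.1 * f, 0.0)] for f in range(5)]
        tracks = tracks_from_positions(pts, max_disp=1e-6)
        assert len(tracks) == 5
        assert all(len(t) == 1 for t in tracks)

    def test_permutation_invariance(self, rng):
        n, l = 12, 8
        base = rng.uniform(0, 10, size=(n, 2))
        frames = [
            [(x + 0.01 * f, y + 0.01 * f) for x, y in base] for f in range(l)
        ]
        t_ref = tracks_from_positions(frames, max_disp=0.2)
        shuffled = [list(pts) for pts in frames]
        for pts in shuffled:
            rng.shuffle(pts)
        t_shuf = tracks_from_positions(shuffled, max_disp=0.2)

        def normalize(tracks):
            return sorted(
                tuple((d.frame, round(d.x_um, 9), round(d.y_um, 9)) for d in t.detections)
                for t in tracks
            )

        assert normalize(t_ref) == normalize(t_shuf)

    def test_identity_swaps_when_jumps_exceed_spacing(self):
        # a/d ~ 1: jumps comparable to the inter-particle distance make
        # nearest-neighbor assignment ambiguous and reconstruction must fail
        # for most trajectories (while all positions are still "detected")
        from spotjump.simulate import GroundTruthTrajectory

        n_full, n_total = 0, 0
        for s in range(20):
            r = np.random.default_rng(1000 + s)
            l, step = 10, 0.3
            starts = [(0.0, 0.0), (0.3, 0.0), (0.0, 0.3), (0.3, 0.3)]
            trajs = []
            for i, (x0, y0) in enumerate(starts):
                dx, dy = r.normal(0, step, l - 1), r.normal(0, step, l - 1)
                trajs.append(
                    GroundTruthTrajectory(
                        i, np.arange(l),
                        x=np.concatenate([[x0], x0 + np.cumsum(dx)]),
                        y=np.concatenate([[y0], y0 + np.cumsum(dy)]),
                        population_label=np.zeros(l, dtype=int),
                    )
                )
            pts = [[(t.x[f], t.y[f]) for t in trajs] for f in range(l)]
            tracks = tracks_from_positions(pts, max_disp=2.0)
            score = score_tracks(tracks, trajs, match_radius_um=1e-6)
            assert score.fraction_detected == 1.0
            n_full += score.fraction_fully_reconstructed * len(trajs)
            n_total += len(trajs)
        assert n_full / n_total < 0.5

    def test_invalid_max_disp(self):
        with pytest.raises(ValueError):
            link_nearest_neighbor([], max_disp_um=0.0)


class TestScoring:
    def _gt(self, rng, n=5, l=10, d=0.05):
        from spotjump.simulate import GroundTruthTrajectory

        trajs = []
        for i in range(n):
            x0, y0 = 2.0 * i, 0.0
            dx = rng.normal(0, d, l - 1)
            dy = rng.normal(0, d, l - 1)
            trajs.append(
                GroundTruthTrajectory(
                    i, np.arange(l),
                    x=np.concatenate([[x0], x0 + np.cumsum(dx)]),
                    y=np.concatenate([[y0], y0 + np.cumsum(dy)]),
                    population_label=np.zeros(l, dtype=int),
                )
            )
        return trajs

    def _tracks_equal_to(self, trajs):
        from spotjump.detect_track import Track

        tracks = []
        for t in trajs:
            dets = [
                Detection(frame=int(f), x_um=float(x), y_um=float(y), intensity=1.0)
                for f, x, y in zip(t.frames, t.x, t.y)
            ]
            tracks.append(Track(id=100 + t.id, detections=dets))
        return tracks

    def test_perfect_tracks_score_one(self, rng):
        trajs = self._gt(rng)
        score = score_tracks(self._tracks_equal_to(trajs), trajs, match_radius_um=0.05)
        assert score.fraction_detected == 1.0
        assert score.fraction_fully_reconstructed == 1.0

    def test_one_broken_link_per_trajectory(self, rng):
        trajs = self._gt(rng)
        tracks = self._tracks_equal_to(trajs)
        split = []
        for k, t in enumerate(tracks):
            from spotjump.detect_track import Track

            split.append(Track(id=2 * k, detections=t.detections[:5]))
            split.append(Track(id=2 * k + 1, detections=t.detections[5:]))
        score = score_tracks(split, trajs, match_radius_um=0.05)
        assert score.fraction_detected == 1.0
        assert score.fraction_fully_reconstructed == 0.0

    def test_foreign_detection_disqualifies(self, rng):
        trajs = self._gt(rng, n=2)
        tracks = self._tracks_equal_to(trajs)
        # append a stray detection to the first track
        tracks[0].detections.append(Detection(frame=10, x_um=50.0, y_um=50.0, intensity=1.0))
        score = score_tracks(tracks, trajs, match_radius_um=0.05)
        assert score.fraction_fully_reconstructed == 0.5

    def test_empty_ground_truth_raises(self):
        with pytest.raises(ValueError):
            score_tracks([], [], match_radius_um=0.05)


class TestEndToEnd:
    def test_noise_free_single_particle_reproduces_gt(self):
        model = ImagingModel(frame_shape=(64, 64), background=0.0, read_noise_sd=0.0, amplitude=100.0)
        cfg = SimulationConfig(
            mix=PopulationMix.single(0.02), imaging=model, n_particles=1, n_frames=15,
            initial_min_spacing_um=1.0, rng_seed=13,
        )
        trajs = simulate_trajectories(cfg)
        stack = render_stack(trajs, model, add_noise=False, n_frames=15)
        params = TrackingParams.for_imaging(model, d_max=0.02, threshold_k=0.0)
        # threshold on a noise-free image: any positive level works
        params = replace(params, threshold_k=1e-6)
        tracks = track_stack(stack, params)
        tracks = [t for t in tracks if len(t) == 15]
        assert len(tracks) == 1
        np.testing.assert_allclose(tracks[0].x_um, trajs[0].x, atol=0.01)
        np.testing.assert_allclose(tracks[0].y_um, trajs[0].y, atol=0.01)
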