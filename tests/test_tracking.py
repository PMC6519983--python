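import math

import numpy as np
import pytest

from branchnet.core import SimParams
from branchnet.imaging import (
    GapModel,
    ImageStack,
    RenderConfig,
    fragment_tracks,
    render_eb1_stack,
    trajectories_from_network,
)
from branchnet.simulate import simulate_sequential
from branchnet.tracking import (
    CometDetection,
    MergeConfig,
    TrackSegment,
    Trajectory,
    detect_comets,
    line_integral_intensity,
    link_comets,
    measure_length_series,
    merge_tracks,
    net_plus_end_speed,
    preprocess_tubulin,
    segments_from_table,
    temporal_median_filter,
)


class TestTemporalMedianFilter:
    def test_static_sequence_vanishes(self, rng):
        frame = rng.random((32, 32)) * 100
        stack = ImageStack(np.repeat(frame[None], 20, axis=0), 0.13, 2.0, "eb1")
        out = temporal_median_filter(stack)
        assert np.allclose(out.data, 0.0)

    def test_moving_spot_survives_background_removed(self):
        T = 31
        data = np.full((T, 32, 64), 50.0)
        for t in range(T):
            data[t, 16, 2 * t : 2 * t + 2] += 500.0
        out = temporal_median_filter(ImageStack(data, 0.13, 2.0, "eb1"))
        # background gone, spot retained at its current position
        assert out.data[15, 16, 30] == pytest.approx(500.0, rel=0.01)
        assert out.data[15, 5, 5] == pytest.approx(0.0, abs=1e-9)

    def test_window_one_zeroes_everything(self, rng):
        stack = ImageStack(rng.random((5, 8, 8)), 0.13, 2.0, "eb1")
        out = temporal_median_filter(stack, window=1)
        assert np.allclose(out.data, 0.0)

    def test_short_stack_warns(self, rng):
        stack = ImageStack(rng.random((5, 8, 8)), 0.13, 2.0, "eb1")
        with pytest.warns(UserWarning, match="truncated"):
            temporal_median_filter(stack, window=15)

    def test_even_window_rejected(self, rng):
        stack = ImageStack(rng.random((20, 8, 8)), 0.13, 2.0, "eb1")
        with pytest.raises(ValueError):
            temporal_median_filter(stack, window=14)


class TestPreprocessTubulin:
    def test_flat_field_removed(self):
        data = np.full((6, 64, 64), 200.0)
        out = preprocess_tubulin(ImageStack(data, 0.13, 2.0, "tubulin"))
        assert np.allclose(out.data, 0.0, atol=1e-6)

    def test_global_bleach_corrected(self, rng):
        # narrow line on offset background decaying as exp(-t/tau)
        T = 30
        base = np.full((64, 64), 100.0)
        base[30:34, :] += 300.0
        decay = np.exp(-np.arange(T) / 20.0)
        data = np.stack([50.0 + base * d for d in decay])
        out = preprocess_tubulin(ImageStack(data, 0.13, 2.0, "tubulin"))
        line = out.data[:, 32, 32]
        late, early = line[-5:].mean(), line[1:6].mean()
        assert late == pytest.approx(early, rel=0.15)

    def test_first_frame_near_zero(self, rng):
        data = rng.random((10, 32, 32))
        out = preprocess_tubulin(ImageStack(data, 0.13, 2.0, "tubulin"))
        assert np.allclose(out.data[0], 0.0, atol=1e-9)


class TestDetection:
    def _stack_with_comets(self, positions, noise_sd=0.0, rng=None):
        net_cfg = RenderConfig()
        data = np.zeros((1, 128, 128))
        s_l, s_s = 10 / 2.3548, 4 / 2.3548
        for (cx, cy) in positions:
            yy, xx = np.mgrid[0:128, 0:128]
            data[0] += 800 * np.exp(
                -((xx - cx) ** 2) / (2 * s_l**2) - ((yy - cy) ** 2) / (2 * s_s**2)
            )
        if noise_sd and rng is not None:
            data += rng.normal(0, noise_sd, data.shape)
        return ImageStack(data, 0.13, 2.0, "eb1")

    def test_single_comet_subpixel(self):
        stack = self._stack_with_comets([(64.3, 50.7)])
        dets = detect_comets(stack, threshold_sd=12)
        assert len(dets) == 1
        assert math.hypot(dets[0].x - 64.3, dets[0].y - 50.7) < 0.5

    def test_blank_frame_no_detections(self, rng):
        stack = ImageStack(rng.normal(0, 1, (1, 64, 64)), 0.13, 2.0, "eb1")
        assert detect_comets(stack) == []

    def test_two_separated_comets(self):
        stack = self._stack_with_comets([(40, 40), (60, 80)])
        assert len(detect_comets(stack)) == 2


class TestLinking:
    def _dets(self, tracks):
        out = []
        for track in tracks:
            for f, x, y in track:
                out.append(CometDetection(f, x, y))
        return out

    def test_single_continuous_track(self):
        dets = self._dets([[(f, 10 + 1.4 * f, 20.0) for f in range(20)]])
        segs = link_comets(dets)
        assert len(segs) == 1
        assert segs[0].frames.tolist() == list(range(20))

    def test_two_tracks_no_swap(self):
        dets = self._dets(
            [
                [(f, 10 + 1.4 * f, 20.0) for f in range(15)],
                [(f, 10 + 1.4 * f, 80.0) for f in range(15)],
            ]
        )
        segs = link_comets(dets)
        assert len(segs) == 2
        for s in segs:
            assert np.ptp(s.xy[:, 1]) < 1e-9

    def test_short_gap_closed_within_radius(self):
        track = [(f, 10 + 1.4 * f, 20.0) for f in range(20) if f != 10]
        segs = link_comets(self._dets([track]))
        assert len(segs) == 1

    def test_spurious_track_discarded(self):
        dets = self._dets([[(0, 50, 50), (1, 50.1, 50.2)]])
        assert link_comets(dets) == []


class TestLineIntegral:
    def test_uniform_image(self):
        img = np.full((32, 32), 7.0)
        assert line_integral_intensity(img, (2, 2), (29, 13)) == pytest.approx(7.0)

    def test_diagonal_sampling_independence(self):
        img = np.full((64, 64), 3.0)
        assert line_integral_intensity(img, (5, 5), (50, 50)) == pytest.approx(3.0)

    def test_zero_length_chord(self):
        img = np.zeros((16, 16))
        img[8, 8] = 42.0
        assert line_integral_intensity(img, (8, 8), (8, 8)) == pytest.approx(42.0)

    def test_on_lattice_brighter_than_off(self):
        img = np.zeros((64, 64))
        img[32, :] = 10.0
        on = line_integral_intensity(img, (5, 32), (55, 32))
        off = line_integral_intensity(img, (5, 10), (55, 10))
        assert on > 10 * max(off, 0.1)


def _seg(id, frames, xy):
    return TrackSegment(id, np.asarray(frames), np.asarray(xy, dtype=float))


def _line_seg(id, f0, n, x0, y0, vx=1.4, vy=0.0):
    frames = np.arange(f0, f0 + n)
    xy = [(x0 + vx * i, y0 + vy * i) for i in range(n)]
    return _seg(id, frames, xy)


def _bright_tubulin(shape=(64, 200)):
    img = np.zeros(shape)
    img[30:35, :] = 10.0
    return img[None]  # single-frame stack


class TestMergeRules:
    def test_single_segment_passthrough(self):
        seg = _line_seg(0, 0, 12, 10, 32)
        out = merge_tracks([seg], _bright_tubulin())
        assert len(out) == 1
        assert out[0].source_segments == [0]

    def test_pause_merge_hand_check(self):
        """Two collinear segments, 4-frame gap, stationary ends, lattice
        present in the gap: merged as a pause."""
        a = _line_seg(0, 0, 10, 10, 32)
        end_x = 10 + 1.4 * 9
        b = _line_seg(1, 14, 10, end_x + 1.0, 32)
        out = merge_tracks([a, b], _bright_tubulin())
        assert len(out) == 1
        assert out[0].gap_classes == ["pause"]
        # gap closed by interpolation: one position per frame
        assert out[0].frames.tolist() == list(range(0, 24))

    def test_cost_prefers_smaller_time_gap(self):
        """Same geometry, t_gap 2 vs 10: the shorter gap wins (1.03^8 ratio)."""
        a = _line_seg(0, 0, 10, 10, 32)
        ex = 10 + 1.4 * 9
        near = _seg(1, np.arange(12, 22), [(ex + 1.0 + 1.4 * i, 32.2) for i in range(10)])
        far = _seg(2, np.arange(20, 30), [(ex + 1.0 + 1.4 * i, 31.8) for i in range(10)])
        out = merge_tracks([a, near, far], _bright_tubulin())
        merged_pairs = [
            (x, y)
            for tr in out
            for x, y in zip(tr.source_segments[:-1], tr.source_segments[1:])
        ]
        assert (0, 1) in merged_pairs

    def test_dark_gap_not_merged(self):
        """A candidate whose gap chord crosses dark background fails the
        lattice-evidence cutoff."""
        img = np.zeros((64, 200))
        img[30:35, :40] = 10.0  # lattice only under the first segment
        a = _seg(0, np.arange(0, 10), [(2 + 1.4 * i, 32.0) for i in range(10)])
        b = _seg(1, np.arange(18, 28), [(60 + 1.4 * i, 32.0) for i in range(10)])
        out = merge_tracks([a, b], img[None])
        assert all(len(tr.source_segments) == 1 for tr in out)

    def test_no_tubulin_only_pause_and_zero_gap(self):
        a = _line_seg(0, 0, 10, 10, 32)
        ex = 10 + 1.4 * 9
        forward = _seg(1, np.arange(14, 24), [(ex + 8 + 1.4 * i, 32.0) for i in range(10)])
        with pytest.warns(UserWarning, match="zero-gap"):
            out = merge_tracks([a, forward], None)
        assert all(len(tr.source_segments) == 1 for tr in out)

    def test_empty_input(self):
        assert merge_tracks([], _bright_tubulin()) == []

    def test_short_trajectories_discarded(self):
        seg = _line_seg(0, 0, 4, 10, 32)
        assert merge_tracks([seg], _bright_tubulin()) == []

    def test_no_fragmentation_identity(self, rng):
        """With zero gap rates merging returns exactly the linked segments."""
        net = simulate_sequential(SimParams(seed=21, t_max=2400, max_mts=8))
        n_frames = int(net.t_end / 2.0) + 1
        times = np.arange(n_frames) * 2.0
        truth = trajectories_from_network(net, times, 0.13, origin_px=(256.0, 256.0))
        gm = GapModel(pause_rate=0, dropout_p=0, catastrophe_rate=0, jitter_sd=0)
        dets, gaps, warped = fragment_tracks(truth, gm, rng)
        segs = segments_from_table(dets)
        out = merge_tracks(segs, _bright_tubulin((512, 512)))
        kept = [s for s in segs if s.end_frame - s.start_frame + 1 >= 6]
        assert len(out) == len(kept)
        assert all(len(tr.source_segments) == 1 for tr in out)


class TestLengthAndSpeed:
    def _traj(self, n=80, speed_px=1.4, jitter=0.0, rng=None):
        xy = np.stack([10 + speed_px * np.arange(n), np.full(n, 32.0)], axis=1)
        if jitter and rng is not None:
            xy = xy + rng.normal(0, jitter, xy.shape)
        return Trajectory(0, np.arange(n), xy)

    def test_straight_track_slope(self):
        tr = self._traj(60)
        lengths = measure_length_series(tr, pixel_size=0.13)
        slope = np.diff(lengths).mean()
        assert slope == pytest.approx(1.4 * 0.13, rel=0.02)

    def test_spline_beats_polyline_under_jitter(self, rng):
        tr = self._traj(100, jitter=1.0, rng=rng)
        true_len = 1.4 * 99 * 0.13
        spline_len = measure_length_series(tr, pixel_size=0.13)[-1]
        poly_len = (
            np.hypot(*np.diff(tr.xy, axis=0).T).sum() * 0.13
        )
        assert abs(spline_len - true_len) / true_len < 0.03
        assert poly_len > spline_len

    def test_stationary_trajectory_zero_length(self):
        tr = Trajectory(0, np.arange(20), np.tile([5.0, 5.0], (20, 1)))
        assert measure_length_series(tr, 0.13)[-1] == pytest.approx(0.0, abs=0.05)

    def test_net_speed_unit_conversion(self):
        # 0.09 um/s at 2 s frames = 1.3846 px/frame at 0.13 um/px
        tr = self._traj(60, speed_px=0.09 * 2 / 0.13)
        v = net_plus_end_speed(tr, 0.13, 2.0)
        assert v == pytest.approx(5.4, rel=0.02)  # um/min

    def test_short_track_excluded(self):
        tr = self._traj(49)
        assert net_plus_end_speed(tr, 0.13, 2.0) is None

    def test_speed_recovery_with_pause(self):
        """A 20% pause time reduces the net speed accordingly."""
        n = 100
        xs = [10.0]
        for f in range(1, n):
            xs.append(xs[-1] + (0.0 if f % 5 == 0 else 1.4))
        tr = Trajectory(0, np.arange(n), np.stack([xs, np.full(n, 32.0)], axis=1))
        v = net_plus_end_speed(tr, 0.13, 2.0)
        v_full = 1.4 * 0.13 / 2.0 * 60.0
        assert v == pytest.approx(0.8 * v_full, rel=0.05)
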