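"""ROI stabilizer: center math, hold/rebuild rule, rates, sweep trends."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from groomkit import detection, roi, scenes


def _boxes_from_centers(centers, size=20.0):
    out = []
    for i, (cx, cy) in enumerate(centers):
        out.append(detection.BoundingBox(i, cx - size / 2, cy - size / 2,
                                         cx + size / 2, cy + size / 2))
    return out


class TestCenterMath:
    @pytest.mark.parametrize("box,expected", [
        ((0, 0, 10, 10), (5, 5)),
        ((100, 200, 150, 260), (125, 230)),
        ((0, 0, 480, 360), (240, 180)),
    ])
    def test_box_center_midpoint(self, box, expected):
        b = detection.BoundingBox(0, *map(float, box))
        c = roi.box_center(b)
        assert (c.x, c.y) == expected

    @pytest.mark.parametrize("a,b,expected", [
        ((0, 0), (3, 4), 5.0),
        ((7, 7), (7, 7), 0.0),
        ((2, 5), (7, 17), 13.0),
    ])
    def test_center_distance_euclidean(self, a, b, expected):
        assert roi.center_distance(roi.CenterPoint(*a),
                                   roi.CenterPoint(*b)) == expected


def brute_force_stabilize(boxes, config, frame_size=None):
    """Independent re-simulation of the hold/rebuild flow, one frame at
    a time, used as the oracle for the vectorized implementation."""
    windows = []
    for i, box in enumerate(boxes):
        if i == 0:
            windows.append(roi._window_from_box(box, config, box.frame_index,
                                                False, frame_size))
            continue
        prev_c = roi.box_center(boxes[i - 1])
        cur_c = roi.box_center(box)
        d = ((cur_c.x - prev_c.x) ** 2 + (cur_c.y - prev_c.y) ** 2) ** 0.5
        if d < config.threshold:
            windows.append(dataclasses.replace(
                windows[-1], frame_index=box.frame_index, changed=False))
        else:
            windows.append(roi._window_from_box(box, config, box.frame_index,
                                                True, frame_size))
    return windows


class TestStabilize:
    def test_all_within_threshold_freezes_window(self):
        centers = [(100 + dx, 100 + dy) for dx, dy in
                   [(0, 0), (3, 1), (-2, 4), (1, -3)] * 5]
        windows = roi.stabilize(_boxes_from_centers(centers),
                                roi.StabilizerConfig(threshold=80))
        first = windows[0]
        assert all((w.x, w.y, w.width, w.height) ==
                   (first.x, first.y, first.width, first.height)
                   for w in windows)
        assert sum(w.changed for w in windows) == 0

    def test_single_jump_rebuilds_once(self):
        thr = 40.0
        centers = [(100.0, 100.0)] * 10 + [(180.0, 100.0)] * 10  # 2x thr jump
        windows = roi.stabilize(_boxes_from_centers(centers),
                                roi.StabilizerConfig(threshold=thr))
        assert [w.changed for w in windows] == \
            [False] * 10 + [True] + [False] * 9
        assert len({(w.x, w.y) for w in windows[:10]}) == 1
        assert len({(w.x, w.y) for w in windows[10:]}) == 1
        assert windows[0].x != windows[10].x

    def test_zero_threshold_tracks_raw_boxes(self, rng):
        centers = rng.uniform(50, 150, size=(30, 2))
        windows = roi.stabilize(_boxes_from_centers(centers),
                                roi.StabilizerConfig(threshold=0.0))
        assert all(w.changed for w in windows[1:])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            roi.stabilize([], roi.StabilizerConfig())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(30, 300), st.floats(30, 300)),
                    min_size=1, max_size=40),
           st.floats(0, 120))
    def test_matches_brute_force_oracle(self, centers, threshold):
        config = roi.StabilizerConfig(threshold=threshold)
        boxes = _boxes_from_centers(centers)
        assert roi.stabilize(boxes, config) == \
            brute_force_stabilize(boxes, config)


class TestCropRois:
    def test_full_frame_window_is_identity(self, rng):
        frame = rng.integers(0, 255, (50, 60, 3), dtype=np.uint8)
        win = roi.ROIWindow(0, 0, 0, 60, 50, False)
        crops = roi.crop_rois([frame], [win])
        assert np.array_equal(crops[0], frame)

    def test_unchanged_run_has_equal_shapes(self, small_config):
        frames, truth = scenes.generate_clip(small_config, "head", 16)
        det = detection.OracleDetector(truth, jitter_sigma=1.0, seed=0)
        boxes = detection.detect_sequence(frames, det)
        windows = roi.stabilize(boxes, roi.StabilizerConfig(threshold=80))
        crops = roi.crop_rois(frames, windows)
        assert len({c.shape for c in crops}) == 1

    def test_out_of_frame_window_edge_padded(self, rng):
        frame = rng.integers(0, 255, (50, 60, 3), dtype=np.uint8)
        win = roi.ROIWindow(0, -10, -5, 30, 20, False)
        crop = roi.crop_rois([frame], [win])[0]
        assert crop.shape == (20, 30, 3)
        assert np.array_equal(crop[5, 10], frame[0, 0])
        assert np.array_equal(crop[0, 0], frame[0, 0])  # edge replication

    def test_misaligned_lengths_rejected(self, rng):
        frame = rng.integers(0, 255, (50, 60, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="windows"):
            roi.crop_rois([frame, frame], [roi.ROIWindow(0, 0, 0, 10, 10,
                                                         False)])


class TestRates:
    def test_stability_rate_formula(self):
        wins = [roi.ROIWindow(i, 0, 0, 10, 10, False) for i in range(10)]
        assert roi.stability_rate(wins) == 1.0
        wins[5] = dataclasses.replace(wins[5], changed=True)
        assert roi.stability_rate(wins) == 0.9

    def test_stationary_subject_full_coverage(self, small_config):
        frames, truth = scenes.generate_clip(small_config, "resting", 16)
        det = detection.OracleDetector(truth, seed=0)
        boxes = detection.detect_sequence(frames, det)
        windows = roi.stabilize(boxes, roi.StabilizerConfig(threshold=80))
        assert roi.coverage_rate(windows, truth) == 1.0

    def test_frozen_window_coverage_equals_exit_fraction(self, small_config):
        """A window held from frame 0 loses the walking subject at the
        analytically known exit frame."""
        n = 40
        _, truth = scenes.generate_clip(small_config, "walking", n)
        boxes = [detection.BoundingBox(i, *truth.boxes[i])
                 for i in range(n)]
        config = roi.StabilizerConfig(threshold=1e9, margin=0.15)
        windows = roi.stabilize(boxes, config)
        # slack before the tight box hits the right window edge
        win = windows[0]
        slack = (win.x + win.width) - truth.boxes[0, 2]
        # frame t is still covered while t * speed <= slack
        n_covered = int(np.floor(slack / small_config.walk_speed)) + 1
        expected = n_covered / n
        assert roi.coverage_rate(windows, truth) == pytest.approx(expected)

    def test_zero_threshold_tracks_and_covers(self, small_config):
        n = 40
        _, truth = scenes.generate_clip(small_config, "walking", n)
        boxes = [detection.BoundingBox(i, *truth.boxes[i]) for i in range(n)]
        windows = roi.stabilize(boxes, roi.StabilizerConfig(threshold=0.0))
        assert roi.coverage_rate(windows, truth) == 1.0


class TestThresholdSweep:
    @pytest.fixture(scope="class")
    @classmethod
    def clip_set(cls):
        config = scenes.SceneConfig(frame_size=(160, 120), subject_size=40,
                                    walk_speed=3.0, seed=21)
        clips = []
        for i in range(4):
            behavior = "head" if i % 2 == 0 else "foreleg"
            frames, truth = scenes.generate_clip(config, behavior, 40,
                                                 rng=np.random.default_rng(i))
            det = detection.OracleDetector(truth, jitter_sigma=2.0, seed=i)
            clips.append(("grooming",
                          detection.detect_sequence(frames, det), truth))
        for i in range(2):
            frames, truth = scenes.generate_clip(
                config, "walking", 40, rng=np.random.default_rng(50 + i))
            det = detection.OracleDetector(truth, jitter_sigma=2.0,
                                           seed=50 + i)
            clips.append(("walking",
                          detection.detect_sequence(frames, det), truth))
        return clips

    def test_stability_monotone_coverage_antitone(self, clip_set):
        table = roi.threshold_sweep(clip_set, [10, 40, 80, 120, 200],
                                    frame_size=(160, 120))
        stab = table["stability_rate"].to_numpy()
        cov = table["coverage_rate"].to_numpy()
        assert np.all(np.diff(stab) >= 0)
        assert np.all(np.diff(cov) <= 0)

    def test_noiseless_grooming_fully_stable(self):
        config = scenes.SceneConfig(frame_size=(160, 120), subject_size=40,
                                    seed=3)
        frames, truth = scenes.generate_clip(config, "head", 32)
        det = detection.OracleDetector(truth, jitter_sigma=0.0, seed=0)
        clips = [("grooming", detection.detect_sequence(frames, det), truth)]
        table = roi.threshold_sweep(clips, [10, 80, 200])
        assert (table["stability_rate"] == 1.0).all()

    def test_empty_threshold_list_rejected(self, clip_set):
        with pytest.raises(ValueError):
            roi.threshold_sweep(clip_set, [])

    def test_per_video_averaging_mode(self, clip_set):
        pooled = roi.threshold_sweep(clip_set, [80], averaging="pooled")
        per_video = roi.threshold_sweep(clip_set, [80],
                                        averaging="per_video")
        # equal-length clips: pooled and per-video means coincide
        assert pooled["stability_rate"][0] == \
            pytest.approx(per_video["stability_rate"][0])


class TestWindowIO:
    def test_roundtrip(self, tmp_path):
        wins = [roi.ROIWindow(i, i * 2, 5, 30, 40, i % 3 == 0)
                for i in range(10)]
        roi.write_windows(wins, tmp_path / "w.csv")
        assert roi.read_windows(tmp_path / "w.csv") == wins
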