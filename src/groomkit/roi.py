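"""Inter-frame ROI stabilization and its selection statistics.

Raw detector boxes jitter in size and position between adjacent frames
even when the subject is perfectly still, which would make the cropped
field of view shake under the 3D classifier. The stabilizer compares
the Euclidean distance between the raw box centers of consecutive
frames with a pixel threshold: below the threshold the previous frame's
window is carried over verbatim (same origin, same size); at or above
it the window is rebuilt from the current raw box. Frame 0 always
builds its window from its own raw box.

Two rates summarize a threshold choice: the *stability rate* of
grooming clips, (count_all - count_change) / count_all, and the body
*coverage rate* of walking clips, (count_all - count_out) / count_all,
where a frame is "out" when the true box is not fully inside the held
window. Raising the threshold trades coverage for stability;
``threshold_sweep`` tabulates both.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .detection import BoundingBox


@dataclasses.dataclass(frozen=True)
class CenterPoint:
    x: float
    y: float


@dataclasses.dataclass(frozen=True)
class ROIWindow:
    """Fixed crop window for one frame (integer pixel grid)."""

    frame_index: int
    x: int
    y: int
    width: int
    height: int
    changed: bool

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("window must have positive extent")

    def contains_box(self, box) -> bool:
        x_min, y_min, x_max, y_max = (
            box.as_tuple() if isinstance(box, BoundingBox) else box)
        return (self.x <= x_min and self.y <= y_min
                and x_max <= self.x + self.width
                and y_max <= self.y + self.height)


@dataclasses.dataclass(frozen=True)
class StabilizerConfig:
    """threshold: center-distance threshold in pixels (default 80);
    margin: fractional expansion of the raw box per side on rebuild."""

    threshold: float = 80.0
    margin: float = 0.15

    def __post_init__(self):
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


@dataclasses.dataclass
class RateCounters:
    count_all: int
    count_change: int
    count_out: int

    def __post_init__(self):
        if not 0 <= self.count_change <= self.count_all:
            raise ValueError("count_change out of range")
        if not 0 <= self.count_out <= self.count_all:
            raise ValueError("count_out out of range")


def box_center(box: BoundingBox) -> CenterPoint:
    """Midpoint of a canonical box in each axis."""
    return CenterPoint((box.x_min + box.x_max) / 2.0,
                       (box.y_min + box.y_max) / 2.0)


def center_distance(a: CenterPoint, b: CenterPoint) -> float:
    return math.hypot(a.x - b.x, a.y - b.y)


def _window_from_box(box: BoundingBox, config: StabilizerConfig,
                     frame_index: int, changed: bool,
                     frame_size=None) -> ROIWindow:
    w = box.x_max - box.x_min
    h = box.y_max - box.y_min
    x0 = box.x_min - config.margin * w
    y0 = box.y_min - config.margin * h
    width = int(round(w * (1 + 2 * config.margin)))
    height = int(round(h * (1 + 2 * config.margin)))
    x0, y0 = int(round(x0)), int(round(y0))
    if frame_size is not None:
        fw, fh = frame_size
        width, height = min(width, fw), min(height, fh)
        x0 = min(max(x0, 0), fw - width)
        y0 = min(max(y0, 0), fh - height)
    return ROIWindow(frame_index, x0, y0, width, height, changed)


def stabilize(boxes: list[BoundingBox], config: StabilizerConfig,
              frame_size=None) -> list[ROIWindow]:
    """Stabilize raw per-frame boxes into held ROI windows.

    The distance test compares *raw* centers of frames t and t-1 (not
    the held window), with strict ``< threshold`` meaning "hold".
    """
    if not boxes:
        raise ValueError("stabilize requires at least one box")
    windows = [_window_from_box(boxes[0], config, boxes[0].frame_index,
                                changed=False, frame_size=frame_size)]
    for prev, box in zip(boxes, boxes[1:]):
        center = box_center(box)
        if center_distance(center, box_center(prev)) < config.threshold:
            held = dataclasses.replace(windows[-1],
                                       frame_index=box.frame_index,
                                       changed=False)
            windows.append(held)
        else:
            windows.append(_window_from_box(box, config, box.frame_index,
                                            changed=True,
                                            frame_size=frame_size))
    return windows


def crop_rois(frames, windows: list[ROIWindow]) -> list[np.ndarray]:
    """Crop each frame to its window, edge-padding at frame borders.

    Within an unchanged run all crops share one shape by construction.
    """
    if len(frames) != len(windows):
        raise ValueError(f"{len(frames)} frames but {len(windows)} windows")
    crops = []
    for frame, win in zip(frames, windows):
        h, w = frame.shape[:2]
        x0, y0 = win.x, win.y
        x1, y1 = x0 + win.width, y0 + win.height
        sx0, sy0 = max(x0, 0), max(y0, 0)
        sx1, sy1 = min(x1, w), min(y1, h)
        if sx0 >= sx1 or sy0 >= sy1:
            raise ValueError(f"window at frame {win.frame_index} lies "
                             "entirely outside the frame")
        crop = frame[sy0:sy1, sx0:sx1]
        pads = ((sy0 - y0, y1 - sy1), (sx0 - x0, x1 - sx1))
        if any(p for pair in pads for p in pair):
            crop = np.pad(crop, pads + ((0, 0),) * (frame.ndim - 2),
                          mode="edge")
        crops.append(crop)
    return crops


def rate_counters(windows: list[ROIWindow],
                  truth_boxes=None) -> RateCounters:
    if not windows:
        raise ValueError("no windows")
    count_all = len(windows)
    count_change = sum(1 for w in windows[1:] if w.changed)
    count_out = 0
    if truth_boxes is not None:
        if len(truth_boxes) != count_all:
            raise ValueError("truth boxes misaligned with windows")
        for win, box in zip(windows, truth_boxes):
            if not win.contains_box(box):
                count_out += 1
    return RateCounters(count_all, count_change, count_out)


def stability_rate(windows: list[ROIWindow]) -> float:
    """(count_all - count_change) / count_all; frame 0 never counts as a
    change (it has no predecessor)."""
    c = rate_counters(windows)
    return (c.count_all - c.count_change) / c.count_all


def coverage_rate(windows: list[ROIWindow], truth) -> float:
    """Fraction of frames whose true box is fully inside the held window."""
    boxes = truth.boxes if hasattr(truth, "boxes") else truth
    c = rate_counters(windows, truth_boxes=np.asarray(boxes))
    return (c.count_all - c.count_out) / c.count_all


def threshold_sweep(clips, thresholds, frame_size=None, margin: float = 0.15,
                    averaging: str = "pooled") -> pd.DataFrame:
    """Stability/coverage rates of a clip set across thresholds.

    ``clips`` is a list of ``(kind, raw_boxes, truth)`` with kind
    "grooming" (contributes to stability) or "walking" (contributes to
    coverage). ``averaging`` is "pooled" (counts pooled over frames of
    all clips, the default) or "per_video" (unweighted mean of per-clip
    rates).
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if averaging not in ("pooled", "per_video"):
        raise ValueError("averaging must be 'pooled' or 'per_video'")
    rows = []
    for thr in thresholds:
        config = StabilizerConfig(threshold=float(thr), margin=margin)
        stab_num = stab_den = cov_num = cov_den = 0.0
        stab_rates, cov_rates = [], []
        for kind, raw_boxes, truth in clips:
            windows = stabilize(raw_boxes, config, frame_size=frame_size)
            if kind == "grooming":
                c = rate_counters(windows)
                stab_num += c.count_all - c.count_change
                stab_den += c.count_all
                stab_rates.append((c.count_all - c.count_change) / c.count_all)
            elif kind == "walking":
                boxes = truth.boxes if hasattr(truth, "boxes") else truth
                c = rate_counters(windows, truth_boxes=np.asarray(boxes))
                cov_num += c.count_all - c.count_out
                cov_den += c.count_all
                cov_rates.append((c.count_all - c.count_out) / c.count_all)
            else:
                raise ValueError(f"unknown clip kind {kind!r}")
        if averaging == "pooled":
            stab = stab_num / stab_den if stab_den else float("nan")
            cov = cov_num / cov_den if cov_den else float("nan")
        else:
            stab = float(np.mean(stab_rates)) if stab_rates else float("nan")
            cov = float(np.mean(cov_rates)) if cov_rates else float("nan")
        rows.append((float(thr), stab, cov))
    return pd.DataFrame(rows, columns=["threshold", "stability_rate",
                                       "coverage_rate"])


def write_windows(windows: list[ROIWindow], path) -> None:
    pd.DataFrame(
        [(w.frame_index, w.x, w.y, w.width, w.height, int(w.changed))
         for w in windows],
        columns=["frame", "x", "y", "width", "height", "changed"],
    ).to_csv(path, index=False)


def read_windows(path) -> list[ROIWindow]:
    df = pd.read_csv(path)
    return [ROIWindow(int(r.frame), int(r.x), int(r.y), int(r.width),
                      int(r.height), bool(r.changed))
            for r in df.itertuples(index=False)]
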