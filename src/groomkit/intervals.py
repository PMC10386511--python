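"""Detection units and their merging into timed behavior intervals.

Continuous video is processed in back-to-back units of 16 consecutive
frames (0.64 s at 25 fps) — short enough that brief grooming bouts are
not missed. Each unit is classified as a whole; maximal runs of
consecutive units with the same label collapse into one behavior
interval with start/end frames and times, yielding the ethogram table.
Times are always derived from frame indices and the true frame rate.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from . import data as data_mod
from . import roi as roi_mod

logger = logging.getLogger(__name__)

UNIT_LEN = 16


@dataclasses.dataclass(frozen=True)
class DetectionUnit:
    unit_index: int
    start_frame: int
    end_frame: int
    label: str
    probabilities: np.ndarray

    def __post_init__(self):
        if self.end_frame - self.start_frame + 1 != UNIT_LEN:
            raise ValueError("a detection unit spans exactly 16 frames")


@dataclasses.dataclass(frozen=True)
class BehaviorInterval:
    behavior: str
    start_frame: int
    end_frame: int
    start_time: float
    end_time: float

    def __post_init__(self):
        if self.end_frame < self.start_frame:
            raise ValueError("interval end before start")


def segment_units(n_frames: int, unit_length: int = UNIT_LEN):
    """Tile ``n_frames`` into floor(n/16) units; the trailing remainder
    is dropped (logged)."""
    if n_frames < unit_length:
        raise ValueError(
            f"need at least {unit_length} frames, got {n_frames}")
    n_units = n_frames // unit_length
    dropped = n_frames - n_units * unit_length
    if dropped:
        logger.info("dropping %d trailing frame(s) shorter than one unit",
                    dropped)
    return [(u * unit_length, (u + 1) * unit_length - 1)
            for u in range(n_units)]


def classify_video(frames, detector, model, stab_config=None,
                   class_names=data_mod.CLASS_NAMES) -> list[DetectionUnit]:
    """Full per-unit pipeline over one continuous video.

    Boxes are detected frame by frame (misses forward-filled), windows
    stabilized with state carried across unit boundaries, each unit's
    crops standardized to 171x128, center-cropped to 112x112,
    mean-subtracted and classified. A unit whose frames were all missed
    by the detector is labeled class 0 with a warning.
    """
    if stab_config is None:
        stab_config = roi_mod.StabilizerConfig()
    bounds = segment_units(len(frames))

    raw = [detector(frame, i) for i, frame in enumerate(frames)]
    dead_units = [ui for ui, (s, e) in enumerate(bounds)
                  if all(raw[i] is None for i in range(s, e + 1))]
    if dead_units:
        warnings.warn(f"detector returned no box for any frame of "
                      f"unit(s) {dead_units}; labeling them "
                      f"{class_names[0]!r}", stacklevel=2)

    filled: list = []
    last = None
    for i, box in enumerate(raw):
        if box is None:
            box = (dataclasses.replace(last, frame_index=i)
                   if last is not None else None)
        else:
            last = box
        filled.append(box)
    first_valid = next((b for b in filled if b is not None), None)
    if first_valid is None:
        filled = None  # whole video undetected; all units -> class 0
    else:
        filled = [b if b is not None
                  else dataclasses.replace(first_valid, frame_index=i)
                  for i, b in enumerate(filled)]
        # unclamped windows keep the subject centered at frame edges;
        # crop_rois edge-pads any overrun
        windows = roi_mod.stabilize(filled, stab_config)

    units = []
    for ui, (start, end) in enumerate(bounds):
        if filled is None or ui in dead_units:
            probs = np.zeros(len(class_names))
            probs[0] = 1.0
            units.append(DetectionUnit(ui, start, end, class_names[0], probs))
            continue
        crops = roi_mod.crop_rois(frames[start:end + 1],
                                  windows[start:end + 1])
        std = data_mod.standardize_frames(crops)
        stack = data_mod.sample_stack(std, 0, train_mode=False)
        label_idx, probs = _predict(model, stack)
        units.append(DetectionUnit(ui, start, end, class_names[label_idx],
                                   probs))
    return units


def _predict(model, stack):
    from .model import predict
    return predict(model, stack)


def merge_units(units: list[DetectionUnit], fps: float = 25.0
                ) -> list[BehaviorInterval]:
    """Run-length merge of consecutive identical unit labels.

    start_time = start_frame / fps; end_time = (end_frame + 1) / fps, so
    durations add up exactly. Concatenating the output intervals
    reproduces the unit label sequence.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    intervals: list[BehaviorInterval] = []
    for unit in units:
        if intervals and intervals[-1].behavior == unit.label:
            prev = intervals[-1]
            intervals[-1] = dataclasses.replace(
                prev, end_frame=unit.end_frame,
                end_time=(unit.end_frame + 1) / fps)
        else:
            intervals.append(BehaviorInterval(
                unit.label, unit.start_frame, unit.end_frame,
                unit.start_frame / fps, (unit.end_frame + 1) / fps))
    return intervals


def detect_ethogram(frames, detector, model, stab_config=None,
                    fps: float = 25.0,
                    class_names=data_mod.CLASS_NAMES):
    """classify_video + merge_units in one call; returns (units,
    intervals)."""
    units = classify_video(frames, detector, model, stab_config,
                           class_names=class_names)
    return units, merge_units(units, fps=fps)


ETHOGRAM_COLUMNS = ["behavior", "start_frame", "end_frame",
                    "start_time_s", "end_time_s"]


def write_ethogram(intervals: list[BehaviorInterval], path) -> None:
    pd.DataFrame(
        [(iv.behavior, iv.start_frame, iv.end_frame, iv.start_time,
          iv.end_time) for iv in intervals],
        columns=ETHOGRAM_COLUMNS).to_csv(path, index=False)


def read_ethogram(path) -> list[BehaviorInterval]:
    """Read an ethogram CSV; overlapping or out-of-order rows are
    rejected naming the offending rows."""
    df = pd.read_csv(path)
    intervals = []
    prev_end = None
    for i, row in enumerate(df.itertuples(index=False), start=2):
        iv = BehaviorInterval(str(row.behavior), int(row.start_frame),
                              int(row.end_frame), float(row.start_time_s),
                              float(row.end_time_s))
        if prev_end is not None and iv.start_frame <= prev_end:
            raise ValueError(
                f"intervals at lines {i - 1} and {i} of {path} overlap "
                "or are out of order")
        prev_end = iv.end_frame
        intervals.append(iv)
    return intervals


def intervals_from_truth(truth_intervals, fps: float = 25.0,
                         pool_non_grooming: bool = True
                         ) -> list[BehaviorInterval]:
    """Ground-truth (behavior, start, end) rows -> BehaviorIntervals.

    With ``pool_non_grooming`` resting/walking map to the "0" category
    (adjacent same-label spans merge), matching the classifier's output
    vocabulary.
    """
    out: list[BehaviorInterval] = []
    for behavior, start, end in truth_intervals:
        label = behavior
        if pool_non_grooming and behavior in ("resting", "walking"):
            label = "0"
        if out and out[-1].behavior == label \
                and out[-1].end_frame + 1 == start:
            out[-1] = dataclasses.replace(out[-1], end_frame=end,
                                          end_time=(end + 1) / fps)
        else:
            out.append(BehaviorInterval(label, start, end, start / fps,
                                        (end + 1) / fps))
    return out
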