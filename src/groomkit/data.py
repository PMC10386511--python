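"""Clip datasets: label indexes, splits, preprocessing and stack sampling.

A labeled corpus is a set of clips, each a directory of frames with a
class label drawn from the fixed seven-category repertoire (index 0 is
the pooled resting-and-walking category). Preprocessing standardizes
every frame to 171x128 (width x height), then samples 16-consecutive-
frame stacks cropped to 112x112 with per-stack RGB mean subtraction —
the ``ClipStack`` unit the classifier consumes. In training mode one
random crop position and one horizontal-flip decision are shared by all
16 frames of a stack; evaluation uses the deterministic center crop and
no flip.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from . import detection, roi, scenes

#: fixed class order; index = position
CLASS_NAMES = ("0", "head", "foreleg", "fore-mid leg", "hind leg",
               "mid-hind leg", "wing")
CLASS_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}

STD_WIDTH, STD_HEIGHT = 171, 128
CROP_SIZE = 112
STACK_LEN = 16


@dataclasses.dataclass(frozen=True)
class ClipRecord:
    clip_id: str
    class_label: str
    frame_dir: Path | None = None
    n_frames: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_INDEX:
            raise ValueError(f"unknown class {self.class_label!r}")

    @property
    def class_index(self) -> int:
        return CLASS_INDEX[self.class_label]


def write_label_index(records, path) -> None:
    """One line per clip: ``<clip_name> <class_index>``."""
    lines = [f"{r.clip_id} {r.class_index}" for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_label_index(path, root=None) -> list[ClipRecord]:
    """Parse a label-index file back into records.

    With ``root`` given, each clip's frame directory is resolved as
    ``root/<class name>/<clip_name>`` and its frames counted.
    """
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(),
                                  start=1):
        if not line.strip():
            continue
        try:
            name, idx_str = line.rsplit(maxsplit=1)
            idx = int(idx_str)
        except ValueError:
            raise ValueError(f"malformed label line {lineno}: {line!r}")
        if not 0 <= idx < len(CLASS_NAMES):
            raise ValueError(
                f"class index {idx} out of range at line {lineno}: {line!r}")
        label = CLASS_NAMES[idx]
        frame_dir, n_frames = None, 0
        if root is not None:
            frame_dir = Path(root) / label / name
            n_frames = len(list(frame_dir.glob("frame_*.png")))
        records.append(ClipRecord(name, label, frame_dir, n_frames))
    return records


def split_train_test(records, ratio=(4, 1), seed: int = 0):
    """Per-class stratified clip-level split.

    The test count per class is the nearest integer to
    ``n * test_share`` with exact halves rounded toward the training
    side; partitions are disjoint and exhaustive. A class with fewer
    than 2 clips goes entirely to train with a warning.
    """
    train_part, test_part = ratio
    test_share = test_part / (train_part + test_part)
    rng = np.random.default_rng(seed)
    by_class: dict[str, list] = {}
    for r in records:
        by_class.setdefault(r.class_label, []).append(r)
    train, test = [], []
    for label in sorted(by_class, key=lambda c: CLASS_INDEX[c]):
        clips = sorted(by_class[label], key=lambda r: r.clip_id)
        if len(clips) < 2:
            warnings.warn(f"class {label!r} has {len(clips)} clip(s); "
                          "keeping all in train", stacklevel=2)
            train.extend(clips)
            continue
        order = rng.permutation(len(clips))
        n_test = math.ceil(len(clips) * test_share - 0.5)  # ties to train
        test_idx = set(order[:n_test].tolist())
        for i, clip in enumerate(clips):
            (test if i in test_idx else train).append(clip)
    return train, test


def standardize_frames(frames) -> np.ndarray:
    """Resize every frame to 171x128 (width x height), bilinear,
    aspect ratio deliberately not preserved."""
    out = np.empty((len(frames), STD_HEIGHT, STD_WIDTH, 3), dtype=np.uint8)
    for i, frame in enumerate(frames):
        if frame.shape[0] == STD_HEIGHT and frame.shape[1] == STD_WIDTH:
            out[i] = frame
        else:
            img = Image.fromarray(np.ascontiguousarray(frame))
            out[i] = np.asarray(
                img.resize((STD_WIDTH, STD_HEIGHT), Image.BILINEAR))
    return out


def sample_stack(std_frames: np.ndarray, start: int, train_mode: bool = False,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Cut one ClipStack: 16 consecutive standardized frames, one shared
    112x112 crop (random in train mode, centered otherwise), one shared
    flip decision (p=0.5, train mode only), per-stack RGB mean
    subtraction. Returns float32 of shape (16, 112, 112, 3).
    """
    n = len(std_frames)
    if start < 0 or start + STACK_LEN > n:
        raise ValueError(
            f"stack [{start}, {start + STACK_LEN}) out of range for "
            f"{n}-frame clip (need at least {STACK_LEN} frames)")
    if train_mode:
        if rng is None:
            raise ValueError("train_mode sampling needs an rng")
        x0 = int(rng.integers(0, STD_WIDTH - CROP_SIZE + 1))
        y0 = int(rng.integers(0, STD_HEIGHT - CROP_SIZE + 1))
        flip = bool(rng.random() < 0.5)
    else:
        x0 = (STD_WIDTH - CROP_SIZE) // 2
        y0 = (STD_HEIGHT - CROP_SIZE) // 2
        flip = False
    stack = std_frames[start:start + STACK_LEN,
                       y0:y0 + CROP_SIZE, x0:x0 + CROP_SIZE]
    stack = stack.astype(np.float32)
    if flip:
        stack = stack[:, :, ::-1]
    stack = stack - stack.mean(axis=(0, 1, 2), keepdims=True,
                               dtype=np.float64).astype(np.float32)
    return np.ascontiguousarray(stack)


def sliding_starts(n_frames: int, stride: int = STACK_LEN,
                   length: int = STACK_LEN) -> list[int]:
    """Start offsets of the sliding 16-frame window over one clip."""
    if n_frames < length:
        return []
    return list(range(0, n_frames - length + 1, stride))


def prepare_roi_frames(frames, raw_boxes, stab_config=None,
                       walking_crop: str = "roi",
                       behavior: str | None = None) -> np.ndarray:
    """Detector boxes -> stabilized windows -> crops -> 171x128 frames.

    ``walking_crop`` selects the walking-set scheme: "roi" (default)
    crops walking clips like everything else; "original" standardizes
    the whole frame for walking clips instead.
    """
    if walking_crop not in ("roi", "original"):
        raise ValueError("walking_crop must be 'roi' or 'original'")
    if stab_config is None:
        stab_config = roi.StabilizerConfig()
    if walking_crop == "original" and behavior == "walking":
        return standardize_frames(frames)
    # windows are deliberately not clamped to the frame: clamping would
    # shift an edge-adjacent subject off-center in the crop (changing
    # the apparent appendage geometry); crop_rois edge-pads overruns
    windows = roi.stabilize(raw_boxes, stab_config)
    crops = roi.crop_rois(frames, windows)
    return standardize_frames(crops)


class StackDataset:
    """In-memory window list over standardized clips.

    Holds ``(std_frames, label)`` clips and enumerates their sliding
    16-frame windows; batches re-sample the augmentation every epoch.
    """

    def __init__(self, clips, stride: int = STACK_LEN):
        self.clips = list(clips)
        self.windows = []  # (clip_idx, start)
        for ci, (std_frames, _label) in enumerate(self.clips):
            for start in sliding_starts(len(std_frames), stride=stride):
                self.windows.append((ci, start))

    def __len__(self):
        return len(self.windows)

    @property
    def labels(self) -> np.ndarray:
        return np.array([self.clips[ci][1] for ci, _ in self.windows])

    def stack(self, index: int, train_mode: bool = False, rng=None):
        ci, start = self.windows[index]
        std_frames, label = self.clips[ci]
        return sample_stack(std_frames, start, train_mode, rng), label

    def batches(self, batch_size: int, train_mode: bool = False, rng=None,
                shuffle: bool = False):
        order = np.arange(len(self.windows))
        if shuffle:
            if rng is None:
                raise ValueError("shuffling needs an rng")
            order = rng.permutation(order)
        for i in range(0, len(order), batch_size):
            idx = order[i:i + batch_size]
            stacks, labels = zip(*(self.stack(j, train_mode, rng)
                                   for j in idx))
            yield np.stack(stacks), np.array(labels)


def make_synthetic_datasets(config: scenes.SceneConfig, classes,
                            clips_per_class: int, n_frames: int,
                            jitter_sigma: float = 2.0,
                            stab_config=None, walking_crop: str = "roi",
                            ratio=(4, 1), stride: int = STACK_LEN,
                            seed: int = 0):
    """Render an in-memory labeled corpus and split it into train/test
    StackDatasets through the full detector -> stabilizer -> crop ->
    standardize pipeline. ``classes`` are folder names ("0" pools
    resting and walking)."""
    master = np.random.default_rng(seed)
    all_clips = []  # (record, std_frames)
    for folder in classes:
        if folder not in CLASS_INDEX:
            raise ValueError(f"unknown class {folder!r}")
        for i in range(clips_per_class):
            clip_seed = int(master.integers(0, 2 ** 31))
            clip_rng = np.random.default_rng(clip_seed)
            behavior = (scenes.NON_GROOMING[i % 2]
                        if folder == scenes.NON_GROOMING_FOLDER else folder)
            frames, truth = scenes.generate_clip(config, behavior, n_frames,
                                                 rng=clip_rng)
            det = detection.OracleDetector(truth, jitter_sigma=jitter_sigma,
                                           seed=clip_seed)
            raw = detection.detect_sequence(frames, det)
            std = prepare_roi_frames(frames, raw, stab_config,
                                     walking_crop=walking_crop,
                                     behavior=behavior)
            rec = ClipRecord(scenes.clip_name(folder, i + 1), folder,
                             n_frames=n_frames)
            all_clips.append((rec, std))
    by_id = {rec.clip_id: std for rec, std in all_clips}
    records = [rec for rec, _ in all_clips]
    train_recs, test_recs = split_train_test(records, ratio=ratio, seed=seed)
    remap = {name: j for j, name in enumerate(sorted(
        {r.class_label for r in records}, key=lambda c: CLASS_INDEX[c]))}
    train = StackDataset([(by_id[r.clip_id], remap[r.class_label])
                          for r in train_recs], stride=stride)
    test = StackDataset([(by_id[r.clip_id], remap[r.class_label])
                         for r in test_recs], stride=stride)
    return train, test, remap
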