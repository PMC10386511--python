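"""Synthetic petri-dish scenes with ground-truth boxes and behavior intervals.

The generator emulates the recording geometry of a single small insect
filmed top-down in a dish: a dark elliptical body with six appendage
blobs, occupying a small fraction of the field of view. Grooming
classes differ by *which* appendage blob oscillates and at what period,
while the body centroid stays put; ``walking`` translates the whole
subject at a constant speed; ``resting`` shows no local motion. Every
clip comes with a tight per-frame bounding box and a behavior-interval
table, so the detector, stabilizer, classifier and interval engine can
all be tested without any real footage.

All randomness flows from a single seed through ``numpy.random.Generator``
instances; a fixed seed reproduces a corpus bit for bit.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

GROOMING_CLASSES = (
    "head",
    "foreleg",
    "fore-mid leg",
    "hind leg",
    "mid-hind leg",
    "wing",
)
NON_GROOMING = ("resting", "walking")
#: folder name for the pooled resting-and-walking category
NON_GROOMING_FOLDER = "0"

# (anchor angles in degrees, oscillation period in frames) per grooming
# class. Grooming is bilaterally symmetric (legs work in left/right
# pairs), so anchors come in mirror pairs about the vertical body axis:
# the rendered classes are invariant under horizontal flips, and remain
# separable by anchor position and oscillation period. y points down,
# so -90 is above the body (head) and +90 below it (wing tips).
_APPENDAGE = {
    "head": ((-90.0,), 6),
    "foreleg": ((-40.0, -140.0), 9),
    "fore-mid leg": ((-10.0, -170.0), 11),
    "hind leg": ((50.0, 130.0), 13),
    "mid-hind leg": ((20.0, 160.0), 15),
    "wing": ((90.0,), 17),
}

_BG_LEVEL = 172.0
_BODY_COLOR = np.array([78.0, 52.0, 40.0])
_BLOB_COLOR = np.array([128.0, 98.0, 56.0])
_ACTIVE_COLOR = np.array([228.0, 204.0, 90.0])

MIN_CLIP_FRAMES = 16


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic recording setup.

    frame_size is (width, height). subject_size is the edge of the tight
    square bounding box; the default 90 px in a 480x360 frame keeps the
    subject at a small fraction of the field of view, mirroring the
    original footage geometry scaled down. walk_speed defaults to
    20 px/frame: with the dish spanning the frame (~35 mm over 480 px),
    that is ~36 mm/s at 25 fps, a realistic pace for an actively
    walking fly and large against detector jitter, so walking is
    distinguishable from box noise by inter-frame center distance.
    """

    frame_size: tuple[int, int] = (480, 360)
    fps: float = 25.0
    subject_size: int = 90
    n_classes: int = 6
    jitter_sigma: float = 0.0
    walk_speed: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if not 2 <= self.n_classes <= 6:
            raise ValueError("n_classes must be between 2 and 6")
        w, h = self.frame_size
        if self.subject_size >= min(w, h):
            raise ValueError("subject must fit inside the frame")

    @property
    def grooming_classes(self) -> tuple[str, ...]:
        return GROOMING_CLASSES[: self.n_classes]

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["frame_size"] = list(self.frame_size)
        Path(path).write_text(yaml.safe_dump(data))

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["frame_size"] = tuple(data["frame_size"])
        return cls(**data)


@dataclasses.dataclass
class GroundTruth:
    """Per-frame tight boxes plus the behavior-interval table.

    boxes is an (n_frames, 4) float array of (x_min, y_min, x_max, y_max)
    half-open pixel boxes; intervals is a list of
    (behavior, start_frame, end_frame) with inclusive ends that tile the
    clip.
    """

    boxes: np.ndarray
    intervals: list[tuple[str, int, int]]

    def __post_init__(self):
        self.boxes = np.asarray(self.boxes, dtype=np.float64)
        prev_end = -1
        for label, start, end in self.intervals:
            if start != prev_end + 1 or end < start:
                raise ValueError("intervals must be sorted, non-overlapping "
                                 "and tile the clip")
            prev_end = end
        if self.intervals and prev_end != len(self.boxes) - 1:
            raise ValueError("intervals must cover every frame")

    @property
    def centers(self) -> np.ndarray:
        return np.stack([(self.boxes[:, 0] + self.boxes[:, 2]) / 2.0,
                         (self.boxes[:, 1] + self.boxes[:, 3]) / 2.0], axis=1)


def _validate_behavior(config: SceneConfig, behavior: str) -> None:
    repertoire = config.grooming_classes + NON_GROOMING
    if behavior not in repertoire:
        raise ValueError(
            f"unknown behavior {behavior!r}; expected one of {repertoire}")


def _background(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = config.frame_size
    cell = 30
    hb, wb = -(-h // cell), -(-w // cell)
    coarse = rng.uniform(-10.0, 10.0, size=(hb, wb))
    tex = np.kron(coarse, np.ones((cell, cell)))[:h, :w]
    frame = np.empty((h, w, 3), dtype=np.float32)
    frame[:] = (_BG_LEVEL + tex)[:, :, None]
    return frame


def _render_segment(config: SceneConfig, behavior: str, n_frames: int,
                    background: np.ndarray, center: np.ndarray,
                    rng: np.random.Generator):
    """Render one constant-behavior segment starting at ``center``.

    Returns (frames uint8 (n,H,W,3), centers float (n,2), end_center).
    """
    w, h = config.frame_size
    s = float(config.subject_size)
    half = s / 2.0
    phase = rng.uniform(0.0, 2.0 * math.pi)

    centers = np.empty((n_frames, 2), dtype=np.float64)
    if behavior == "walking":
        # straight-line track, reflected at the walls so the box stays
        # inside the frame; short clips fit without any reflection
        margin = half + 2.0
        target = np.array([w / 2.0, h / 2.0])
        direction = target - center
        norm = np.hypot(*direction)
        angle = (rng.uniform(0, 2 * math.pi) if norm < 1.0
                 else math.atan2(direction[1], direction[0]))
        vel = config.walk_speed * np.array([math.cos(angle), math.sin(angle)])
        pos = center.astype(np.float64).copy()
        for t in range(n_frames):
            centers[t] = pos
            pos = pos + vel
            for axis, hi in ((0, w), (1, h)):
                if pos[axis] < margin:
                    pos[axis] = 2 * margin - pos[axis]
                    vel[axis] = -vel[axis]
                elif pos[axis] > hi - margin:
                    pos[axis] = 2 * (hi - margin) - pos[axis]
                    vel[axis] = -vel[axis]
    else:
        centers[:] = center

    frames = np.empty((n_frames, h, w, 3), dtype=np.uint8)
    body_a, body_b = 0.22 * s, 0.30 * s  # ellipse semi-axes (x, y)
    blob_r0, blob_amp, blob_sigma = 0.26 * s, 0.08 * s, 0.045 * s
    anchors = {name: _APPENDAGE[name] for name in config.grooming_classes}

    for t in range(n_frames):
        cx, cy = centers[t]
        frame = background.copy()
        x0 = max(int(cx - half) - 2, 0)
        x1 = min(int(cx + half) + 3, w)
        y0 = max(int(cy - half) - 2, 0)
        y1 = min(int(cy + half) + 3, h)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        patch = frame[y0:y1, x0:x1]

        body = (((xs - cx) / body_a) ** 2 + ((ys - cy) / body_b) ** 2) <= 1.0
        patch[body] = _BODY_COLOR

        for name, (angles, period) in anchors.items():
            active = name == behavior
            r = blob_r0
            if active:
                r = blob_r0 + blob_amp * math.sin(
                    2.0 * math.pi * t / period + phase)
            color = _ACTIVE_COLOR if active else _BLOB_COLOR
            for angle_deg in angles:
                ang = math.radians(angle_deg)
                bx = cx + r * math.cos(ang)
                by = cy + r * math.sin(ang)
                d2 = (xs - bx) ** 2 + (ys - by) ** 2
                weight = np.exp(-d2 / (2.0 * blob_sigma ** 2))[:, :, None]
                patch += weight * (color - patch)

        frames[t] = np.clip(frame, 0, 255).astype(np.uint8)

    boxes_centers = centers
    end_center = centers[-1].copy() if behavior == "walking" else center
    return frames, boxes_centers, end_center


def _boxes_from_centers(config: SceneConfig, centers: np.ndarray) -> np.ndarray:
    half = config.subject_size / 2.0
    return np.stack([centers[:, 0] - half, centers[:, 1] - half,
                     centers[:, 0] + half, centers[:, 1] + half], axis=1)


def _random_center(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    w, h = config.frame_size
    margin = config.subject_size / 2.0 + 2.0
    return np.array([rng.uniform(margin, w - margin),
                     rng.uniform(margin, h - margin)])


def generate_clip(config: SceneConfig, behavior: str, n_frames: int,
                  rng: np.random.Generator | None = None):
    """Render a single constant-behavior clip.

    Returns ``(frames, GroundTruth)`` where frames is a
    ``(n_frames, H, W, 3)`` uint8 array.
    """
    if n_frames < MIN_CLIP_FRAMES:
        raise ValueError(
            f"n_frames must be at least {MIN_CLIP_FRAMES} (one detection "
            f"unit); got {n_frames}")
    _validate_behavior(config, behavior)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    background = _background(config, rng)
    w, h = config.frame_size
    if behavior == "walking":
        margin = config.subject_size / 2.0 + 2.0
        center = np.array([margin + 1.0, h / 2.0])
    else:
        center = _random_center(config, rng)
    frames, centers, _ = _render_segment(config, behavior, n_frames,
                                         background, center, rng)
    truth = GroundTruth(boxes=_boxes_from_centers(config, centers),
                        intervals=[(behavior, 0, n_frames - 1)])
    return frames, truth


def generate_session(config: SceneConfig, script: list[tuple[str, int]],
                     rng: np.random.Generator | None = None):
    """Render a continuous multi-behavior video from a behavior script.

    ``script`` is a list of ``(behavior, n_frames)`` segments executed
    back to back; the subject position persists across segments (walking
    moves it, grooming/resting keep it where the last segment ended).
    """
    if not script:
        raise ValueError("script must contain at least one segment")
    for behavior, n in script:
        _validate_behavior(config, behavior)
        if n < 1:
            raise ValueError("segment length must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    background = _background(config, rng)
    center = _random_center(config, rng)
    all_frames, all_centers, intervals = [], [], []
    cursor = 0
    for behavior, n in script:
        frames, centers, center = _render_segment(
            config, behavior, n, background, center, rng)
        all_frames.append(frames)
        all_centers.append(centers)
        intervals.append((behavior, cursor, cursor + n - 1))
        cursor += n
    centers = np.concatenate(all_centers)
    truth = GroundTruth(boxes=_boxes_from_centers(config, centers),
                        intervals=intervals)
    return np.concatenate(all_frames), truth


# ---------------------------------------------------------------------------
# corpus generation on disk
# ---------------------------------------------------------------------------

def class_folders(config: SceneConfig) -> list[str]:
    """Per-class folder names: grooming classes plus the pooled "0"."""
    return list(config.grooming_classes) + [NON_GROOMING_FOLDER]


def corpus_plan(clips_per_class, classes) -> dict[str, int]:
    """Resolve a per-class clip-count plan without rendering anything."""
    if isinstance(clips_per_class, dict):
        missing = [c for c in classes if c not in clips_per_class]
        if missing:
            raise ValueError(f"no clip count for classes {missing}")
        return {c: int(clips_per_class[c]) for c in classes}
    n = int(clips_per_class)
    if n < 1:
        raise ValueError("clips_per_class must be at least 1")
    return {c: n for c in classes}


def clip_name(folder: str, index: int) -> str:
    """Behavior name + number, whitespace-free for label-index files."""
    return f"{folder.replace(' ', '_')}{index:03d}"


def write_ground_truth(truth: GroundTruth, boxes_path, intervals_path) -> None:
    boxes = pd.DataFrame(truth.boxes,
                         columns=["x_min", "y_min", "x_max", "y_max"])
    boxes.insert(0, "frame", np.arange(len(boxes)))
    boxes.to_csv(boxes_path, index=False)
    pd.DataFrame(truth.intervals,
                 columns=["behavior", "start_frame", "end_frame"]
                 ).to_csv(intervals_path, index=False)


def read_ground_truth(boxes_path, intervals_path) -> GroundTruth:
    boxes = pd.read_csv(boxes_path).sort_values("frame")
    intervals = [
        (str(r.behavior), int(r.start_frame), int(r.end_frame))
        for r in pd.read_csv(intervals_path).itertuples()]
    return GroundTruth(
        boxes=boxes[["x_min", "y_min", "x_max", "y_max"]].to_numpy(),
        intervals=intervals)


def write_clip_frames(frames: np.ndarray, clip_dir: Path) -> None:
    clip_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(frames):
        iio.imwrite(clip_dir / f"frame_{i:05d}.png", frame)


def read_clip_frames(clip_dir) -> np.ndarray:
    paths = sorted(Path(clip_dir).glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frames found under {clip_dir}")
    return np.stack([iio.imread(p) for p in paths])


def generate_corpus(config: SceneConfig, clips_per_class, out_dir,
                    len_range: tuple[float, float] = (7.0, 10.0),
                    classes: list[str] | None = None):
    """Render a labeled clip corpus on disk, one folder per class.

    Clip lengths are drawn uniformly from ``len_range`` seconds. Clips of
    the pooled "0" class alternate between resting and walking. Returns a
    list of ``(clip_id, class_folder, clip_dir, n_frames)`` tuples.
    Deterministic for a fixed ``config.seed``.
    """
    out_dir = Path(out_dir)
    if classes is None:
        classes = class_folders(config)
    plan = corpus_plan(clips_per_class, classes)
    master = np.random.default_rng(config.seed)
    manifest = []
    for folder in classes:
        for i in range(1, plan[folder] + 1):
            clip_seed = int(master.integers(0, 2 ** 31))
            clip_rng = np.random.default_rng(clip_seed)
            n_frames = max(MIN_CLIP_FRAMES, int(round(
                clip_rng.uniform(*len_range) * config.fps)))
            if folder == NON_GROOMING_FOLDER:
                behavior = NON_GROOMING[i % 2]  # alternate resting/walking
            else:
                behavior = folder
            frames, truth = generate_clip(config, behavior, n_frames,
                                          rng=clip_rng)
            name = clip_name(folder, i)
            clip_dir = out_dir / folder / name
            write_clip_frames(frames, clip_dir)
            write_ground_truth(truth, clip_dir / "boxes.csv",
                               clip_dir / "intervals.csv")
            manifest.append((name, folder, clip_dir, n_frames))
    return manifest
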