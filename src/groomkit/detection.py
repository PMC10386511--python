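"""Per-frame body-region boxes through a pluggable detector contract.

The original system localizes the insect body with a trained object
detector; here the detector is an interface: any callable
``detector(frame, frame_index) -> BoundingBox | None`` can be plugged
in (an adapter for a real detector only needs to return its
highest-confidence detection per frame). The bundled
:class:`OracleDetector` perturbs ground-truth boxes with Gaussian edge
jitter and Bernoulli misses, emulating the frame-to-frame inconsistency
of real detections that motivates the ROI stabilizer.

Coordinates are 0-based with x rightward and y downward; boxes are
half-open ``[x_min, x_max) x [y_min, y_max)``.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BOX_COLUMNS = ["frame", "x_min", "y_min", "x_max", "y_max"]


@dataclasses.dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned detection box in canonical (min, max) form."""

    frame_index: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0
    label: str = "subject"

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box at frame {self.frame_index}: "
                f"({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})")

    @property
    def corners(self):
        """Vertices (top-left, top-right, bottom-right, bottom-left)."""
        return ((self.x_min, self.y_min), (self.x_max, self.y_min),
                (self.x_max, self.y_max), (self.x_min, self.y_max))

    @classmethod
    def from_corners(cls, frame_index, corners, **kwargs):
        xs = [c[0] for c in corners]
        ys = [c[1] for c in corners]
        return cls(frame_index, min(xs), min(ys), max(xs), max(ys), **kwargs)

    def clamped(self, frame_size) -> "BoundingBox":
        w, h = frame_size
        return dataclasses.replace(
            self,
            x_min=max(0.0, min(self.x_min, w - 1.0)),
            y_min=max(0.0, min(self.y_min, h - 1.0)),
            x_max=max(1.0, min(self.x_max, float(w))),
            y_max=max(1.0, min(self.y_max, float(h))))

    def as_tuple(self):
        return (self.x_min, self.y_min, self.x_max, self.y_max)


def best_detection(candidates):
    """Pick one detection: highest confidence, ties to larger area,
    then to earlier list position."""
    if not candidates:
        return None
    best = candidates[0]
    for box in candidates[1:]:
        area = (box.x_max - box.x_min) * (box.y_max - box.y_min)
        best_area = (best.x_max - best.x_min) * (best.y_max - best.y_min)
        if (box.confidence, area) > (best.confidence, best_area):
            best = box
    return best


class OracleDetector:
    """Ground-truth-backed detector with Gaussian jitter and misses.

    Each box edge is perturbed independently with N(0, jitter_sigma);
    a frame is missed (returns None) with probability ``miss_rate``.
    Deterministic for a fixed seed: the perturbations for all frames are
    drawn once at construction.
    """

    def __init__(self, truth, jitter_sigma: float = 0.0,
                 miss_rate: float = 0.0, seed: int = 0):
        if jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if not 0.0 <= miss_rate < 1.0:
            raise ValueError("miss_rate must be in [0, 1)")
        boxes = np.asarray(truth.boxes, dtype=np.float64)
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, jitter_sigma, size=boxes.shape)
        self._boxes = boxes + noise
        self._missed = rng.random(len(boxes)) < miss_rate
        # jitter may invert a box at extreme draws; re-order to stay canonical
        x_lo = np.minimum(self._boxes[:, 0], self._boxes[:, 2] - 1e-6)
        x_hi = np.maximum(self._boxes[:, 2], self._boxes[:, 0] + 1e-6)
        y_lo = np.minimum(self._boxes[:, 1], self._boxes[:, 3] - 1e-6)
        y_hi = np.maximum(self._boxes[:, 3], self._boxes[:, 1] + 1e-6)
        self._boxes = np.stack([x_lo, y_lo, x_hi, y_hi], axis=1)

    def __call__(self, frame, frame_index: int):
        if self._missed[frame_index]:
            return None
        x_min, y_min, x_max, y_max = self._boxes[frame_index]
        return BoundingBox(frame_index, x_min, y_min, x_max, y_max)

    @property
    def n_misses(self) -> int:
        return int(self._missed.sum())


def detect_sequence(frames, detector) -> list[BoundingBox]:
    """Run a detector over every frame, forward-filling missed frames.

    A miss re-uses the last accepted box (with a warning); a miss on the
    very first frame has nothing to fill from and is an error.
    """
    boxes: list[BoundingBox] = []
    n_filled = 0
    for i, frame in enumerate(frames):
        box = detector(frame, i)
        if box is None:
            if not boxes:
                raise ValueError("detector missed frame 0; no box to "
                                 "forward-fill from")
            box = dataclasses.replace(boxes[-1], frame_index=i)
            n_filled += 1
        boxes.append(box)
    if n_filled:
        logger.warning("forward-filled %d missed detection(s)", n_filled)
        warnings.warn(f"forward-filled {n_filled} missed detection(s)",
                      stacklevel=2)
    return boxes


def write_boxes(boxes, path) -> None:
    rows = [(b.frame_index, b.x_min, b.y_min, b.x_max, b.y_max)
            for b in boxes]
    pd.DataFrame(rows, columns=BOX_COLUMNS).to_csv(path, index=False)


def read_boxes(path) -> list[BoundingBox]:
    """Read a box CSV; malformed or inverted rows raise with the 1-based
    data line number."""
    df = pd.read_csv(path)
    missing = [c for c in BOX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"box CSV {path} lacks columns {missing}")
    boxes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            boxes.append(BoundingBox(int(row.frame), float(row.x_min),
                                     float(row.y_min), float(row.x_max),
                                     float(row.y_max)))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid box at line {i} of {path}: {exc}")
    return boxes
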