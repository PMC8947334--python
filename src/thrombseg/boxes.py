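"""Bounding-box construction, training-box sampling, and the dynamic
bounding-box algorithm (moving + flexible methods).

The initial box is placed around the detected occlusion point with fixed
offsets: 15 voxels cranially (axis 0, increasing index = cranial), 65
caudally, and 24 to each side on both lateral axes -- an unclamped size of
81 x 49 x 49 with the point's own slice included.  The box proportions are
meant to enclose ~90% of thrombi when the detection point is accurate.

When the detection point is poor the initial box may miss the thrombus
partly or entirely.  Two refinements address this:

* *moving*: if the in-box prediction is small (< 100 voxels), the box is
  translated by floor(2/3 of its extent) along each of the six axis
  directions, the predictor is re-run on every candidate, and the candidate
  (original included) with the largest predicted volume wins; ties go to
  the earliest candidate in a fixed order, so results are deterministic.
* *flexible*: any box face with predicted voxels within 5 voxels of it is
  pushed outward by 10 voxels and the predictor re-run, up to 5 times.

Boxes are clamped (cropped) at grid boundaries; zero padding at network
input compensates for the reduced extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np


class BoxError(ValueError):
    """Raised on invalid box geometry or inputs."""


Predictor = Callable[["BoundingBox"], np.ndarray]
"""A predictor maps a (clamped) box to a boolean mask of the box's shape."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned voxel box, half-open [start, stop) per axis."""

    start: Tuple[int, int, int]
    stop: Tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", tuple(int(s) for s in self.start))
        object.__setattr__(self, "stop", tuple(int(s) for s in self.stop))
        if any(a >= b for a, b in zip(self.start, self.stop)):
            raise BoxError(f"degenerate box {self.start}..{self.stop}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))  # type: ignore[return-value]

    @property
    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))  # type: ignore[return-value]

    def contains_point(self, point: Sequence[int]) -> bool:
        return all(a <= p < b for p, a, b in zip(point, self.start, self.stop))

    def clamp(self, grid_shape: Sequence[int]) -> "BoundingBox":
        start = tuple(min(max(a, 0), g - 1) for a, g in zip(self.start, grid_shape))
        stop = tuple(max(min(b, g), s + 1) for b, g, s in zip(self.stop, grid_shape, start))
        return BoundingBox(start, stop)

    def translate(self, axis: int, delta: int) -> "BoundingBox":
        start = list(self.start)
        stop = list(self.stop)
        start[axis] += delta
        stop[axis] += delta
        return BoundingBox(tuple(start), tuple(stop))

    def extract(self, grid: np.ndarray) -> np.ndarray:
        return grid[self.slices]

    def to_json(self) -> Dict[str, List[int]]:
        return {f"axis{i}": [self.start[i], self.stop[i]] for i in range(3)}

    @staticmethod
    def from_json(obj: Dict[str, List[int]]) -> "BoundingBox":
        start = tuple(obj[f"axis{i}"][0] for i in range(3))
        stop = tuple(obj[f"axis{i}"][1] for i in range(3))
        return BoundingBox(start, stop)  # type: ignore[arg-type]


@dataclass(frozen=True)
class InitialBoxConfig:
    """Offsets from the detection point to the initial-box faces (voxels)."""

    cranial_offset: int = 15
    caudal_offset: int = 65
    lateral_offset: int = 24

    def __post_init__(self) -> None:
        if min(self.cranial_offset, self.caudal_offset, self.lateral_offset) < 0:
            raise BoxError("offsets must be >= 0")

    @property
    def unclamped_shape(self) -> Tuple[int, int, int]:
        lon = self.caudal_offset + self.cranial_offset + 1
        lat = 2 * self.lateral_offset + 1
        return (lon, lat, lat)


@dataclass(frozen=True)
class DynamicBoxConfig:
    """Gates and step sizes of the moving and flexible box methods."""

    small_prediction_threshold: int = 100
    move_fraction: float = 2.0 / 3.0
    edge_proximity: int = 5
    growth_step: int = 10
    max_flexible_iterations: int = 5

    def __post_init__(self) -> None:
        if self.small_prediction_threshold <= 0:
            raise BoxError("threshold must be > 0")
        if not 0 < self.move_fraction <= 1:
            raise BoxError("move fraction must be in (0, 1]")
        if self.growth_step <= 0 or self.max_flexible_iterations < 1:
            raise BoxError("bad growth parameters")


@dataclass(frozen=True)
class TrainingBoxConfig:
    """Per-side random offsets for training-box augmentation.

    For each factor ``n`` one box is sampled: starting from the tight box
    around the ground truth, each of the six sides is pushed outward by an
    independent uniform draw from (-0.1 x tight extent, n x initial-box
    extent) along that side's axis (negative draws shrink the box).
    """

    offset_factors: Tuple[float, ...] = (0.2, 0.3, 0.5, 0.7, 0.9)
    shrink_fraction: float = 0.1
    initial_box: InitialBoxConfig = InitialBoxConfig()

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.offset_factors):
            raise BoxError("offset factors must be > 0")


def make_initial_box(
    point: Sequence[int],
    grid_shape: Sequence[int],
    cfg: InitialBoxConfig | None = None,
) -> BoundingBox:
    """Initial box around the detection point, clamped to the grid.

    Unclamped, the box spans [point - caudal, point + cranial + 1) along
    axis 0 and [point - lateral, point + lateral + 1) along axes 1 and 2:
    81 x 49 x 49 with the defaults.
    """
    cfg = cfg or InitialBoxConfig()
    if not all(0 <= p < g for p, g in zip(point, grid_shape)):
        raise BoxError(f"point {tuple(point)} outside grid {tuple(grid_shape)}")
    start = (
        point[0] - cfg.caudal_offset,
        point[1] - cfg.lateral_offset,
        point[2] - cfg.lateral_offset,
    )
    stop = (
        point[0] + cfg.cranial_offset + 1,
        point[1] + cfg.lateral_offset + 1,
        point[2] + cfg.lateral_offset + 1,
    )
    return BoundingBox(start, stop).clamp(grid_shape)


def tight_box(mask: np.ndarray) -> BoundingBox:
    """Smallest box enclosing all true voxels of a boolean grid."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise BoxError("mask is empty")
    return BoundingBox(tuple(idx.min(axis=0)), tuple(idx.max(axis=0) + 1))


def sample_training_boxes(
    gt: np.ndarray,
    cfg: TrainingBoxConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> List[BoundingBox]:
    """Sample one augmented training box per offset factor (five by default)."""
    cfg = cfg or TrainingBoxConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tight = tight_box(np.asarray(gt, dtype=bool))
    extents = np.array(tight.shape, dtype=float)
    init_extents = np.array(cfg.initial_box.unclamped_shape, dtype=float)
    boxes = []
    for n in cfg.offset_factors:
        start = list(tight.start)
        stop = list(tight.stop)
        for axis in range(3):
            lo = -cfg.shrink_fraction * extents[axis]
            hi = n * init_extents[axis]
            start[axis] -= int(round(rng.uniform(lo, hi)))
            stop[axis] += int(round(rng.uniform(lo, hi)))
            if stop[axis] <= start[axis]:  # guarantee non-empty
                mid = (tight.start[axis] + tight.stop[axis]) // 2
                start[axis], stop[axis] = mid, mid + 1
        boxes.append(BoundingBox(tuple(start), tuple(stop)).clamp(gt.shape))
    return boxes


@dataclass
class CropRecord:
    """Remembers the pre-padding shape so predictions can be un-padded."""

    original_shape: Tuple[int, int, int]
    padded_shape: Tuple[int, int, int]


def acceptable_size(extent: int, depth: int) -> int:
    """Smallest multiple of 2**depth that is >= extent."""
    unit = 2**depth
    return int(np.ceil(extent / unit)) * unit


def pad_to_acceptable(
    crop: np.ndarray, depth: int
) -> Tuple[np.ndarray, CropRecord]:
    """Zero-pad spatial extents (last 3 axes) up to multiples of 2**depth.

    Padding is appended at the high end of each axis; the returned record
    allows exact un-padding of a prediction back to the original box shape.
    """
    if depth < 1:
        raise BoxError("depth must be >= 1")
    spatial = crop.shape[-3:]
    target = tuple(acceptable_size(e, depth) for e in spatial)
    pad = [(0, 0)] * (crop.ndim - 3) + [(0, t - e) for t, e in zip(target, spatial)]
    padded = np.pad(crop, pad)
    return padded, CropRecord(tuple(spatial), target)  # type: ignore[arg-type]


def unpad(prediction: np.ndarray, record: CropRecord) -> np.ndarray:
    """Crop a padded prediction back to the original box shape."""
    d, h, w = record.original_shape
    return prediction[..., :d, :h, :w]


def moving_box(
    box: BoundingBox,
    predictor: Predictor,
    cfg: DynamicBoxConfig | None = None,
    grid_shape: Sequence[int] | None = None,
    prediction: np.ndarray | None = None,
) -> Tuple[BoundingBox, np.ndarray, dict]:
    """Translate the box towards a larger prediction when it is nearly empty.

    If the prediction inside ``box`` already has at least the small-prediction
    threshold of voxels, the box is returned untouched.  Otherwise the box is
    shifted by floor(move_fraction x extent) along each of +-axis 0/1/2, the
    predictor is evaluated on every (clamped) candidate, and the candidate
    with the largest predicted voxel count wins; ties break towards the
    earliest candidate in the order (original, +0, -0, +1, -1, +2, -2).
    """
    cfg = cfg or DynamicBoxConfig()
    if prediction is None:
        prediction = predictor(box)
    n0 = int(np.count_nonzero(prediction))
    info = {"activated": False, "initial_voxels": n0, "candidates": []}
    if n0 >= cfg.small_prediction_threshold:
        return box, prediction, info

    info["activated"] = True
    extent = box.shape
    candidates: List[Tuple[BoundingBox, np.ndarray]] = [(box, prediction)]
    for axis in range(3):
        step = int(np.floor(cfg.move_fraction * extent[axis]))
        for sign in (+1, -1):
            cand = box.translate(axis, sign * step)
            if grid_shape is not None:
                cand = cand.clamp(grid_shape)
            candidates.append((cand, predictor(cand)))
    counts = [int(np.count_nonzero(p)) for _, p in candidates]
    info["candidates"] = [
        {"box": b.to_json(), "voxels": c} for (b, _), c in zip(candidates, counts)
    ]
    best = int(np.argmax(counts))  # argmax keeps the first of tied maxima
    box, prediction = candidates[best]
    return box, prediction, info


def _faces_near_prediction(
    prediction: np.ndarray, proximity: int
) -> List[Tuple[int, int]]:
    """Faces (axis, side) with a predicted voxel closer than ``proximity``.

    side 0 is the start (low-index) face, side 1 the stop face.  Distance is
    the number of voxel steps from the predicted voxel to the face, so a
    voxel lying on the face has distance 0.
    """
    idx = np.argwhere(prediction)
    if idx.size == 0:
        return []
    faces = []
    for axis in range(3):
        extent = prediction.shape[axis]
        if idx[:, axis].min() < proximity:
            faces.append((axis, 0))
        if (extent - 1 - idx[:, axis].max()) < proximity:
            faces.append((axis, 1))
    return faces


def flexible_box(
    box: BoundingBox,
    prediction: np.ndarray,
    predictor: Predictor,
    cfg: DynamicBoxConfig | None = None,
    grid_shape: Sequence[int] | None = None,
) -> Tuple[BoundingBox, np.ndarray, dict]:
    """Grow faces the prediction presses against, re-predicting each time.

    While any predicted voxel lies closer than ``edge_proximity`` voxel steps
    to a box face and fewer than ``max_flexible_iterations`` growths have
    happened, every such face moves outward by ``growth_step`` voxels
    (clamped to the grid) and the predictor runs on the enlarged box.  The
    box only ever grows; if clamping stops all growth the loop ends early.
    """
    cfg = cfg or DynamicBoxConfig()
    info = {"iterations": 0, "history": []}
    for _ in range(cfg.max_flexible_iterations):
        faces = _faces_near_prediction(prediction, cfg.edge_proximity)
        if not faces:
            break
        start = list(box.start)
        stop = list(box.stop)
        for axis, side in faces:
            if side == 0:
                start[axis] -= cfg.growth_step
            else:
                stop[axis] += cfg.growth_step
        grown = BoundingBox(tuple(start), tuple(stop))
        if grid_shape is not None:
            grown = grown.clamp(grid_shape)
        if grown == box:  # every touched face already at the grid boundary
            break
        box = grown
        prediction = predictor(box)
        info["iterations"] += 1
        info["history"].append(
            {"box": box.to_json(), "voxels": int(np.count_nonzero(prediction))}
        )
    return box, prediction, info


def dynamic_box(
    point: Sequence[int],
    grid_shape: Sequence[int],
    predictor: Predictor,
    init_cfg: InitialBoxConfig | None = None,
    dyn_cfg: DynamicBoxConfig | None = None,
    use_moving: bool = True,
    use_flexible: bool = True,
) -> Tuple[BoundingBox, np.ndarray, dict]:
    """Full dynamic-box pipeline: initial box, moving stage, flexible stage.

    Returns the final box, the final prediction embedded in a full-grid
    boolean mask, and a provenance record of every stage sufficient to
    replay the box sequence.
    """
    init_cfg = init_cfg or InitialBoxConfig()
    dyn_cfg = dyn_cfg or DynamicBoxConfig()
    box = make_initial_box(point, grid_shape, init_cfg)
    prediction = predictor(box)
    provenance: dict = {
        "initial_box": box.to_json(),
        "initial_voxels": int(np.count_nonzero(prediction)),
    }
    if use_moving:
        box, prediction, info = moving_box(
            box, predictor, dyn_cfg, grid_shape=grid_shape, prediction=prediction
        )
        provenance["moving"] = info
    if use_flexible:
        box, prediction, info = flexible_box(
            box, prediction, predictor, dyn_cfg, grid_shape=grid_shape
        )
        provenance["flexible"] = info
    provenance["final_box"] = box.to_json()
    full = np.zeros(tuple(grid_shape), dtype=bool)
    full[box.slices] = prediction
    return box, full, provenance
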