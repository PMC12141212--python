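"""Axis-aligned boxes, the IOU, and the normalized (YOLO-dialect) coordinates.

Coordinate convention: continuous pixel coordinates with the origin at the
top-left corner, x increasing rightward and y downward.  A box covers the
half-open rectangle [x_min, x_max) x [y_min, y_max) and its area is simply
width x height — no "+1 pixel" correction, which keeps the pixel and the
normalized representations exact inverses of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Box",
    "NormalizedBox",
    "Detection",
    "StackDetections",
    "CellLabelMap",
    "iou",
    "normalized_to_pixel",
    "pixel_to_normalized",
]


@dataclass(frozen=True)
class Box:
    """An axis-aligned rectangle in pixel coordinates with strictly positive area."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise InvalidInputError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, "
                f"{self.y_max}) must satisfy x_max > x_min and y_max > y_min"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes.

    Returns a ratio in [0, 1]: 0 for disjoint boxes, 1 for identical ones.
    Symmetric in its arguments.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


@dataclass(frozen=True)
class NormalizedBox:
    """YOLO-dialect box: center and size as fractions of the image dimensions."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise InvalidInputError(f"class_id must be non-negative, got {self.class_id}")
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidInputError(f"{name}={v} outside [0, 1]")
        if self.w <= 0.0 or self.h <= 0.0:
            raise InvalidInputError(f"normalized box must have w > 0 and h > 0, got w={self.w}, h={self.h}")


def normalized_to_pixel(nb: NormalizedBox, width: int, height: int) -> Box:
    """Convert a normalized box to pixel coordinates, clamping to the image.

    A box that protrudes beyond the image edge is clamped; one that lies
    entirely outside the image (possible only through rounding pathologies)
    raises :class:`InvalidInputError`.
    """
    if width <= 0 or height <= 0:
        raise InvalidInputError(f"image dimensions must be positive, got {width}x{height}")
    x_min = (nb.cx - nb.w / 2.0) * width
    x_max = (nb.cx + nb.w / 2.0) * width
    y_min = (nb.cy - nb.h / 2.0) * height
    y_max = (nb.cy + nb.h / 2.0) * height
    x_min, x_max = max(x_min, 0.0), min(x_max, float(width))
    y_min, y_max = max(y_min, 0.0), min(y_max, float(height))
    if x_max <= x_min or y_max <= y_min:
        raise InvalidInputError("box lies entirely outside the image after conversion")
    return Box(x_min, y_min, x_max, y_max)


def pixel_to_normalized(box: Box, width: int, height: int, class_id: int = 0) -> NormalizedBox:
    """Inverse of :func:`normalized_to_pixel` for boxes inside the image."""
    if width <= 0 or height <= 0:
        raise InvalidInputError(f"image dimensions must be positive, got {width}x{height}")
    cx, cy = box.center
    return NormalizedBox(
        class_id=class_id,
        cx=cx / width,
        cy=cy / height,
        w=box.width / width,
        h=box.height / height,
    )


@dataclass(frozen=True)
class Detection:
    """One detected object in one focal plane."""

    box: Box
    confidence: float = 1.0
    slice_index: int = 0
    class_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise InvalidInputError(f"confidence {self.confidence} outside [0, 1]")
        if self.slice_index < 0:
            raise InvalidInputError(f"slice_index must be non-negative, got {self.slice_index}")
        if self.class_id < 0:
            raise InvalidInputError(f"class_id must be non-negative, got {self.class_id}")


@dataclass
class StackDetections:
    """Per-slice detections for one focal stack, ordered by focal depth."""

    image_width: int
    image_height: int
    slices: list[list[Detection]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise InvalidInputError(
                f"image dimensions must be positive, got {self.image_width}x{self.image_height}"
            )
        for i, dets in enumerate(self.slices):
            for d in dets:
                if d.slice_index != i:
                    raise InvalidInputError(
                        f"detection carries slice_index {d.slice_index} but sits in slice {i}"
                    )

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def n_detections(self) -> int:
        return sum(len(s) for s in self.slices)

    def per_slice_counts(self) -> list[int]:
        return [len(s) for s in self.slices]


class CellLabelMap:
    """Instance-segmentation raster: 0 = background, k >= 1 = pixels of cell k.

    Wraps the integer label image emitted by Cellpose-style segmenters.  Cell
    ids are labels, not ranks: non-contiguous id sets are preserved verbatim.
    """

    def __init__(self, data: np.ndarray):
        arr = np.asarray(data)
        if arr.ndim != 2:
            raise InvalidInputError(f"label map must be 2D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            raise InvalidInputError(f"label map must be integer-valued, got dtype {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise InvalidInputError("label map contains negative values")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # (rows, cols) = (height, width)

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def cell_ids(self) -> list[int]:
        ids = np.unique(self.data)
        return [int(i) for i in ids if i > 0]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CellLabelMap) and np.array_equal(self.data, other.data)
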