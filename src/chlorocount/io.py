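"""Readers and writers for detection files, label maps, and detection tables.

Detection files follow the YOLO annotation dialect: one object per line,
whitespace-separated ``class cx cy w h [confidence]`` with coordinates
normalized to the image dimensions.  Ground-truth files carry five fields
(confidence defaults to 1.0); prediction files carry six.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .boxes import (
    Box,
    CellLabelMap,
    Detection,
    NormalizedBox,
    StackDetections,
    normalized_to_pixel,
    pixel_to_normalized,
)
from .errors import FormatError, InvalidInputError, ParseError

__all__ = [
    "read_detection_text",
    "read_detection_file",
    "write_detection_file",
    "read_label_map",
    "write_label_map",
    "detections_to_frame",
    "write_detections_csv",
]

# printed precision of normalized coordinates; 6 decimals on [0,1] keeps the
# round-trip exact to ~1e-6 px on images below ~1e6 px across
_COORD_FMT = "{:.6f}"


def read_detection_text(
    text: str, width: int, height: int, slice_index: int = 0
) -> list[Detection]:
    """Parse YOLO-dialect annotation text into pixel-coordinate detections.

    Each non-empty line must hold 5 fields (class cx cy w h) or 6 fields
    (... confidence).  Line order is preserved.  Malformed lines raise
    :class:`ParseError` naming the 1-based line number.
    """
    detections: list[Detection] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise ParseError(
                f"line {lineno}: expected 5 or 6 fields, got {len(fields)}: {line!r}"
            )
        try:
            class_id = int(fields[0])
            cx, cy, w, h = (float(v) for v in fields[1:5])
            confidence = float(fields[5]) if len(fields) == 6 else 1.0
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        try:
            nb = NormalizedBox(class_id=class_id, cx=cx, cy=cy, w=w, h=h)
            box = normalized_to_pixel(nb, width, height)
            det = Detection(
                box=box, confidence=confidence, slice_index=slice_index, class_id=class_id
            )
        except InvalidInputError as exc:
            raise InvalidInputError(f"line {lineno}: {exc}") from None
        detections.append(det)
    return detections


def read_detection_file(
    path: str | os.PathLike, width: int, height: int, slice_index: int = 0
) -> list[Detection]:
    """Read one per-slice YOLO-dialect annotation file."""
    text = Path(path).read_text(encoding="utf-8")
    return read_detection_text(text, width, height, slice_index=slice_index)


def write_detection_file(
    path: str | os.PathLike,
    detections: list[Detection],
    width: int,
    height: int,
    include_confidence: bool = True,
) -> None:
    """Write detections back to the YOLO text dialect (inverse of the reader)."""
    lines = []
    for det in detections:
        nb = pixel_to_normalized(det.box, width, height, class_id=det.class_id)
        parts = [str(nb.class_id)] + [_COORD_FMT.format(v) for v in (nb.cx, nb.cy, nb.w, nb.h)]
        if include_confidence:
            parts.append(_COORD_FMT.format(det.confidence))
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_label_map(path: str | os.PathLike) -> CellLabelMap:
    """Load an instance label map from TIFF, PNG, or a .npy array dump.

    The file must contain a single-channel integer image; float-valued or
    multi-channel input raises :class:`FormatError`.
    """
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    elif suffix == ".npy":
        arr = np.load(p, allow_pickle=False)
    elif suffix == ".png":
        arr = iio.imread(p)
    else:
        raise FormatError(f"unsupported label-map format: {suffix!r} (use TIFF, PNG, or .npy)")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"label map must be single-channel 2D, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"label map must be integer-valued, got dtype {arr.dtype}")
    return CellLabelMap(arr)


def write_label_map(path: str | os.PathLike, labels: CellLabelMap) -> None:
    """Write a label map as TIFF, PNG (16-bit), or .npy depending on suffix."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(p, labels.data.astype(np.int32))
    elif suffix == ".npy":
        np.save(p, labels.data)
    elif suffix == ".png":
        if labels.data.size and labels.data.max() > np.iinfo(np.uint16).max:
            raise FormatError("label ids exceed 16-bit PNG range; use TIFF or .npy")
        iio.imwrite(p, labels.data.astype(np.uint16))
    else:
        raise FormatError(f"unsupported label-map format: {suffix!r}")


def detections_to_frame(stack: StackDetections) -> pd.DataFrame:
    """Flatten a stack into a table: slice, class, x_min, y_min, x_max, y_max, confidence."""
    rows = [
        {
            "slice": det.slice_index,
            "class": det.class_id,
            "x_min": det.box.x_min,
            "y_min": det.box.y_min,
            "x_max": det.box.x_max,
            "y_max": det.box.y_max,
            "confidence": det.confidence,
        }
        for dets in stack.slices
        for det in dets
    ]
    return pd.DataFrame(
        rows, columns=["slice", "class", "x_min", "y_min", "x_max", "y_max", "confidence"]
    )


def write_detections_csv(path: str | os.PathLike, stack: StackDetections) -> None:
    detections_to_frame(stack).to_csv(path, index=False)
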