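"""Detection stage: a classical blob detector and a bridge for external predictions.

The pipeline is detector-agnostic.  Predictions from any trained model (YOLO
or otherwise) enter through :func:`load_external_predictions` as per-slice
YOLO-dialect text files.  For use without trained weights, a deliberately
simple classical detector is provided: Gaussian smoothing, a global threshold
(Otsu or fixed, polarity-aware), connected components, an area filter, and a
tight bounding box per surviving component.  It exists to exercise the
pipeline end to end; stronger detectors plug in via ``StackDetections``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .boxes import Box, Detection, StackDetections
from .errors import FormatError, InvalidInputError
from .io import read_detection_file

__all__ = ["BlobDetectorParams", "detect_blobs", "load_external_predictions"]


@dataclass(frozen=True)
class BlobDetectorParams:
    smoothing_sigma: float = 1.0  # px
    threshold_mode: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: float = 0.5  # intensity in [0,1], used when mode == "fixed"
    min_area: float = 30.0  # px^2
    max_area: float = 4000.0  # px^2
    polarity: str = "bright"  # "bright" | "dark": blobs brighter/darker than background

    def __post_init__(self) -> None:
        if self.smoothing_sigma < 0:
            raise InvalidInputError(f"smoothing_sigma must be >= 0, got {self.smoothing_sigma}")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise InvalidInputError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not (0.0 <= self.fixed_threshold <= 1.0):
            raise InvalidInputError(f"fixed_threshold {self.fixed_threshold} outside [0, 1]")
        if not (0 <= self.min_area < self.max_area):
            raise InvalidInputError(
                f"need 0 <= min_area < max_area, got {self.min_area}, {self.max_area}"
            )
        if self.polarity not in ("bright", "dark"):
            raise InvalidInputError(f"unknown polarity {self.polarity!r}")


def detect_blobs(
    image: np.ndarray,
    params: BlobDetectorParams | None = None,
    slice_index: int = 0,
) -> list[Detection]:
    """Detect compact blobs in one grayscale slice.

    Confidence is the normalized component contrast: the component's peak
    smoothed intensity minus the mean background intensity (sign-flipped for
    dark polarity), clipped to [0, 1].  Peak rather than mean contrast keeps
    defocused objects — whose above-threshold footprint is dominated by dim
    halo pixels — comparable to in-focus ones.  A constant image under Otsu
    thresholding yields zero detections.
    """
    params = params or BlobDetectorParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise FormatError(f"detect_blobs expects a 2D grayscale image, got shape {img.shape}")

    smoothed = ndimage.gaussian_filter(img, params.smoothing_sigma) if params.smoothing_sigma > 0 else img
    if params.threshold_mode == "otsu":
        if np.ptp(smoothed) == 0.0:
            return []
        thr = threshold_otsu(smoothed)
    else:
        thr = params.fixed_threshold
    mask = smoothed > thr if params.polarity == "bright" else smoothed < thr
    if not mask.any():
        return []

    background_mean = float(smoothed[~mask].mean()) if (~mask).any() else 0.0
    labeled = cc_label(mask, connectivity=2)
    detections: list[Detection] = []
    for region in regionprops(labeled, intensity_image=smoothed):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        min_row, min_col, max_row, max_col = region.bbox
        if params.polarity == "dark":
            contrast = background_mean - float(region.intensity_min)
        else:
            contrast = float(region.intensity_max) - background_mean
        confidence = float(np.clip(contrast, 0.0, 1.0))
        detections.append(
            Detection(
                box=Box(float(min_col), float(min_row), float(max_col), float(max_row)),
                confidence=confidence,
                slice_index=slice_index,
            )
        )
    return detections


_TRAILING_INT = re.compile(r"(\d+)(?!.*\d)")


def load_external_predictions(
    directory: str | Path,
    width: int,
    height: int,
    manifest: Sequence[str] | None = None,
) -> StackDetections:
    """Assemble per-slice YOLO-dialect text files into a StackDetections.

    Without a manifest, files are taken in lexicographic order and, when every
    stem embeds a slice number, the numbering must be gap-free (a missing
    slice would silently break focal adjacency).  A manifest — an ordered
    sequence of file names relative to ``directory`` — overrides both.
    """
    directory = Path(directory)
    if manifest is not None:
        paths = [directory / name for name in manifest]
        missing = [str(p) for p in paths if not p.is_file()]
        if missing:
            raise InvalidInputError(f"manifest names missing files: {missing}")
    else:
        paths = sorted(directory.glob("*.txt"))
        if not paths:
            raise InvalidInputError(f"no .txt detection files in {directory} (a stack needs >= 1 slice)")
        numbers = [_TRAILING_INT.search(p.stem) for p in paths]
        if all(numbers):
            seen = sorted(int(m.group(1)) for m in numbers)  # type: ignore[union-attr]
            expected = list(range(seen[0], seen[0] + len(seen)))
            if seen != expected:
                gaps = sorted(set(range(seen[0], seen[-1] + 1)) - set(seen))
                raise InvalidInputError(
                    f"gap in slice numbering in {directory}: missing slices {gaps} "
                    "(pass an explicit manifest to override)"
                )
    slices = [
        read_detection_file(p, width, height, slice_index=i) for i, p in enumerate(paths)
    ]
    return StackDetections(image_width=width, image_height=height, slices=slices)
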