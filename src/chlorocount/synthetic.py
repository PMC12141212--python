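"""Synthetic multi-focal-plane stacks of cells with elliptical chloroplasts.

The generator emulates a bright-field/fluorescence z-series of a leaf field:
the image is partitioned into cells (a seeded Voronoi tessellation, optional
background margin at the border), each cell receives a known number of
elliptical chloroplasts placed strictly inside it, and every chloroplast is
assigned a continuous depth z within the stack.  Rendering one slice applies
a defocus model per chloroplast,

    sigma(z, slice) = sigma0 + blur_slope * |z - z_slice|,

as a Gaussian blur of the in-focus ellipse, together with intensity
attenuation 1 / (1 + attenuation * |z - z_slice|) and a small zero-mean
lateral jitter that mimics stage drift during focus adjustment.  A
chloroplast is *visible* in a slice iff its blur sigma there is at most
``visibility_sigma``; only visible instances emit ground-truth boxes, so
chloroplasts genuinely vanish from far-away planes — the regime that makes
naive per-slice counting wrong and cross-slice deduplication necessary.

All randomness flows from the single seed in :class:`SceneSpec`; the same
spec reproduces bit-identical stacks and ground truth.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .boxes import Box, CellLabelMap, Detection, StackDetections
from .errors import InvalidInputError
from .io import write_detection_file, write_label_map

__all__ = ["SceneSpec", "Chloroplast", "GroundTruth", "generate_scene", "oracle_stack", "write_scene"]


@dataclass(frozen=True)
class SceneSpec:
    """Study conditions for one simulated field of view.

    Defaults emulate a 60x light-microscope field: a five-plane series (the
    typical series length of such acquisitions), four cells, chloroplast
    semi-axes of 4-7 px, mild defocus growth between planes, ~1 px stage
    jitter, and low sensor noise.
    """

    image_width: int = 320
    image_height: int = 320
    n_slices: int = 5
    n_cells: int = 4
    border_margin: int = 6  # px of background frame around the tessellation
    counts: tuple[int, ...] | None = None  # explicit per-cell counts, else drawn
    count_range: tuple[int, int] = (5, 20)  # inclusive, used when counts is None
    axis_range: tuple[float, float] = (4.0, 7.0)  # ellipse semi-axes, px
    sigma0: float = 0.8  # in-focus blur, px
    blur_slope: float = 1.5  # px of extra blur per slice of defocus
    visibility_sigma: float = 2.5  # blur beyond which a chloroplast is invisible
    attenuation: float = 0.3  # intensity falloff per slice of defocus
    jitter_px: float = 1.0  # std of per-slice lateral displacement
    noise_scale: float = 0.01  # std of additive Gaussian background noise
    min_separation: float = 18.0  # min center-to-center distance between chloroplasts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise InvalidInputError("n_slices must be >= 1")
        if self.n_cells < 1:
            raise InvalidInputError("n_cells must be >= 1")
        if self.jitter_px < 0:
            raise InvalidInputError("jitter_px must be >= 0")
        if not (0 < self.axis_range[0] <= self.axis_range[1]):
            raise InvalidInputError(f"bad axis_range {self.axis_range}")
        if self.counts is None and not (0 <= self.count_range[0] <= self.count_range[1]):
            raise InvalidInputError(f"bad count_range {self.count_range}")
        if self.counts is not None and len(self.counts) != self.n_cells:
            raise InvalidInputError(
                f"counts has {len(self.counts)} entries for {self.n_cells} cells"
            )
        if self.visibility_sigma < self.sigma0:
            raise InvalidInputError("visibility_sigma below sigma0 would hide every chloroplast")


@dataclass(frozen=True)
class Chloroplast:
    """One simulated chloroplast in the registry."""

    chl_id: int
    cell_id: int
    center: tuple[float, float]  # (x, y), px
    axes: tuple[float, float]  # semi-axes (a along x, b along y), px
    z: float  # depth in slice units, in [0, n_slices - 1]


@dataclass
class GroundTruth:
    """Everything the generator knows: the answer key for every other module."""

    spec: SceneSpec
    chloroplasts: list[Chloroplast]
    slice_boxes: list[list[tuple[int, Box]]]  # per slice: (chl_id, visible box)
    label_map: CellLabelMap
    per_cell_counts: dict[int, int]

    @property
    def n_chloroplasts(self) -> int:
        return len(self.chloroplasts)


def _tessellate(spec: SceneSpec, rng: np.random.Generator) -> CellLabelMap:
    """Seeded Voronoi partition: each interior pixel joins its nearest seed.

    Seeds sit on a jittered grid so the resulting cells are balanced in area
    regardless of the random seed.
    """
    h, w, m = spec.image_height, spec.image_width, spec.border_margin
    g = int(math.ceil(math.sqrt(spec.n_cells)))
    pitch_x = (w - 2 * m) / g
    pitch_y = (h - 2 * m) / g
    seeds: list[tuple[float, float]] = []
    for i in range(spec.n_cells):
        gx, gy = i % g, i // g
        x = m + (gx + 0.5) * pitch_x + rng.uniform(-0.2, 0.2) * pitch_x
        y = m + (gy + 0.5) * pitch_y + rng.uniform(-0.2, 0.2) * pitch_y
        seeds.append((x, y))
    ys, xs = np.mgrid[0:h, 0:w]
    d2 = np.stack(
        [(xs + 0.5 - sx) ** 2 + (ys + 0.5 - sy) ** 2 for sx, sy in seeds], axis=0
    )
    labels = np.argmin(d2, axis=0).astype(np.int32) + 1
    if m > 0:
        labels[:m, :] = 0
        labels[-m:, :] = 0
        labels[:, :m] = 0
        labels[:, -m:] = 0
    return CellLabelMap(labels)


def _place_chloroplasts(
    spec: SceneSpec, rng: np.random.Generator, labels: CellLabelMap
) -> list[Chloroplast]:
    counts = (
        list(spec.counts)
        if spec.counts is not None
        else [int(rng.integers(spec.count_range[0], spec.count_range[1] + 1)) for _ in range(spec.n_cells)]
    )
    h, w = labels.shape
    ys, xs = np.mgrid[0:h, 0:w]
    # pixels still far enough from every placed chloroplast center
    separated = np.ones((h, w), dtype=bool)
    placed: list[Chloroplast] = []
    chl_id = 0
    for cell_idx, n in enumerate(counts, start=1):
        mask = labels.data == cell_idx
        # distance to the cell boundary: the whole ellipse must fit inside
        edt = ndimage.distance_transform_edt(mask)
        for _ in range(n):
            a = float(rng.uniform(*spec.axis_range))
            b = float(rng.uniform(*spec.axis_range))
            margin = max(a, b) + 1.0
            rows, cols = np.nonzero((edt > margin) & separated)
            if rows.size == 0:
                raise InvalidInputError(
                    f"cell {cell_idx} cannot fit {n} chloroplasts of semi-axes "
                    f"up to {spec.axis_range[1]} px at min_separation "
                    f"{spec.min_separation} px"
                )
            j = int(rng.integers(rows.size))
            x = float(cols[j]) + float(rng.uniform(0, 1))
            y = float(rows[j]) + float(rng.uniform(0, 1))
            separated &= ((xs + 0.5 - x) ** 2 + (ys + 0.5 - y) ** 2) >= spec.min_separation**2
            z = float(rng.uniform(0, spec.n_slices - 1)) if spec.n_slices > 1 else 0.0
            placed.append(
                Chloroplast(chl_id=chl_id, cell_id=cell_idx, center=(x, y), axes=(a, b), z=z)
            )
            chl_id += 1
    return placed


def _render_ellipse(
    image: np.ndarray, cx: float, cy: float, a: float, b: float, sigma: float, amp: float
) -> None:
    """Add one defocused ellipse into ``image`` in place."""
    h, w = image.shape
    half = int(math.ceil(max(a, b) + 4.0 * sigma)) + 2
    x0, x1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
    y0, y1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    ex = ((xs - cx) / a) ** 2
    ey = ((ys - cy) / b) ** 2
    patch = (ey[:, None] + ex[None, :] <= 1.0).astype(float) * amp
    if sigma > 0:
        patch = ndimage.gaussian_filter(patch, sigma)
    # clip the patch to the image
    ty0, ty1 = max(y0, 0), min(y1, h)
    tx0, tx1 = max(x0, 0), min(x1, w)
    if ty0 >= ty1 or tx0 >= tx1:
        return
    image[ty0:ty1, tx0:tx1] += patch[ty0 - y0 : ty1 - y0, tx0 - x0 : tx1 - x0]


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a z-stack and its complete ground truth.

    Returns ``(stack, truth)`` where ``stack`` has shape
    (n_slices, height, width) with intensities in [0, 1].  Deterministic for
    a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    labels = _tessellate(spec, rng)
    chloroplasts = _place_chloroplasts(spec, rng, labels)

    h, w = spec.image_height, spec.image_width
    stack = np.zeros((spec.n_slices, h, w), dtype=float)
    slice_boxes: list[list[tuple[int, Box]]] = [[] for _ in range(spec.n_slices)]

    for s in range(spec.n_slices):
        img = stack[s]
        for chl in chloroplasts:
            # draw jitter unconditionally so the random stream does not depend
            # on visibility decisions
            dx = float(rng.normal(0.0, spec.jitter_px)) if spec.jitter_px > 0 else 0.0
            dy = float(rng.normal(0.0, spec.jitter_px)) if spec.jitter_px > 0 else 0.0
            dz = abs(chl.z - s)
            sigma = spec.sigma0 + spec.blur_slope * dz
            if sigma > spec.visibility_sigma:
                continue
            amp = 1.0 / (1.0 + spec.attenuation * dz)
            cx, cy = chl.center[0] + dx, chl.center[1] + dy
            a, b = chl.axes
            _render_ellipse(img, cx, cy, a, b, sigma, amp)
            # ground-truth box: ellipse extents dilated by the blur scale,
            # clamped to the image; a jittered box fully outside is dropped
            x0, x1 = max(cx - (a + sigma), 0.0), min(cx + (a + sigma), float(w))
            y0, y1 = max(cy - (b + sigma), 0.0), min(cy + (b + sigma), float(h))
            if x1 <= x0 or y1 <= y0:
                continue
            slice_boxes[s].append((chl.chl_id, Box(x0, y0, x1, y1)))
        if spec.noise_scale > 0:
            img += rng.normal(0.0, spec.noise_scale, size=img.shape)
    np.clip(stack, 0.0, 1.0, out=stack)

    per_cell: dict[int, int] = {cid: 0 for cid in labels.cell_ids}
    for chl in chloroplasts:
        per_cell[chl.cell_id] += 1
    truth = GroundTruth(
        spec=spec,
        chloroplasts=chloroplasts,
        slice_boxes=slice_boxes,
        label_map=labels,
        per_cell_counts=per_cell,
    )
    return stack, truth


def oracle_stack(truth: GroundTruth) -> StackDetections:
    """Ground-truth boxes repackaged as perfect detections (confidence 1.0)."""
    slices = [
        [Detection(box=box, confidence=1.0, slice_index=s) for _cid, box in boxes]
        for s, boxes in enumerate(truth.slice_boxes)
    ]
    return StackDetections(
        image_width=truth.spec.image_width,
        image_height=truth.spec.image_height,
        slices=slices,
    )


def write_scene(
    out_dir: str | os.PathLike, stack: np.ndarray, truth: GroundTruth
) -> Path:
    """Persist a scene: 16-bit TIFF slices, YOLO-txt truth, label map, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w, h = truth.spec.image_width, truth.spec.image_height
    for s in range(stack.shape[0]):
        tifffile.imwrite(
            out / f"slice_{s:03d}.tif", (stack[s] * 65535).astype(np.uint16)
        )
        dets = [
            Detection(box=box, confidence=1.0, slice_index=s)
            for _cid, box in truth.slice_boxes[s]
        ]
        write_detection_file(
            out / f"slice_{s:03d}.txt", dets, w, h, include_confidence=False
        )
    write_label_map(out / "labels.tif", truth.label_map)
    payload = {
        "spec": asdict(truth.spec),
        "n_chloroplasts": truth.n_chloroplasts,
        "per_cell_counts": {str(k): v for k, v in truth.per_cell_counts.items()},
        "chloroplasts": [asdict(c) for c in truth.chloroplasts],
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return out
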