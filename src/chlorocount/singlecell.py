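"""Attribute detections to individual cells and build per-cell profiles.

A cell instance label map (from Cellpose or any instance segmenter) assigns
each detection to a cell by the label under the detection box's center point.
Center-point containment is cheap, deterministic, and robust to boxes that
slightly overhang thin cell walls.  For 3D entries, which carry one box per
slice, the cell is decided by majority vote over the history with ties broken
by the earliest-slice assignment.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .boxes import Box, CellLabelMap, Detection
from .dedup import Benchmark
from .errors import InvalidInputError

__all__ = [
    "CellProfile",
    "assign_cell",
    "per_cell_counts_2d",
    "per_cell_counts_3d",
    "cell_areas",
    "cell_centroids",
    "border_cell_ids",
]


@dataclass(frozen=True)
class CellProfile:
    cell_id: int
    area_px: int
    chloroplast_count: int
    centroid: tuple[float, float]  # (x, y) in pixel coordinates


def assign_cell(box: Box, labels: CellLabelMap) -> int:
    """Cell id at the box center (0 = background / unassigned).

    The center is mapped to the pixel containing it; centers on the far edge
    of the raster fall into the last pixel.  Centers outside the raster raise.
    """
    cx, cy = box.center
    h, w = labels.shape
    if not (0.0 <= cx <= w and 0.0 <= cy <= h):
        raise InvalidInputError(
            f"box center ({cx:.2f}, {cy:.2f}) outside label map extent {w}x{h}"
        )
    col = min(int(math.floor(cx)), w - 1)
    row = min(int(math.floor(cy)), h - 1)
    return int(labels.data[row, col])


def cell_areas(labels: CellLabelMap) -> dict[int, int]:
    """Pixel area per cell id (ids preserved, background excluded)."""
    ids, counts = np.unique(labels.data, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts) if i > 0}


def cell_centroids(labels: CellLabelMap) -> dict[int, tuple[float, float]]:
    """Mean pixel-center coordinate (x, y) per cell id."""
    out: dict[int, tuple[float, float]] = {}
    for cid in labels.cell_ids:
        rows, cols = np.nonzero(labels.data == cid)
        out[cid] = (float(cols.mean()) + 0.5, float(rows.mean()) + 0.5)
    return out


def _build_profiles(
    labels: CellLabelMap, counts: dict[int, int]
) -> list[CellProfile]:
    areas = cell_areas(labels)
    centroids = cell_centroids(labels)
    return [
        CellProfile(
            cell_id=cid,
            area_px=areas[cid],
            chloroplast_count=counts.get(cid, 0),
            centroid=centroids[cid],
        )
        for cid in labels.cell_ids
    ]


def per_cell_counts_2d(
    detections: list[Detection], labels: CellLabelMap
) -> tuple[list[CellProfile], int]:
    """Per-cell chloroplast counts for one slice.

    Returns one profile per cell id present in the map (count 0 if no
    detection fell inside) plus the number of detections whose center landed
    on background.  Counts partition the detections:
    sum(per-cell counts) + background = len(detections).
    """
    counts: Counter[int] = Counter()
    background = 0
    for det in detections:
        cid = assign_cell(det.box, labels)
        if cid == 0:
            background += 1
        else:
            counts[cid] += 1
    return _build_profiles(labels, dict(counts)), background


def _vote_cell(entry_history: list, labels: CellLabelMap) -> int:
    """Majority vote over an entry's per-slice boxes; earliest slice breaks ties."""
    votes = [(slice_index, assign_cell(box, labels)) for slice_index, box, _conf in entry_history]
    tally = Counter(cid for _s, cid in votes)
    top = max(tally.values())
    tied = {cid for cid, n in tally.items() if n == top}
    if len(tied) == 1:
        return tied.pop()
    for _s, cid in votes:  # history is slice-ordered
        if cid in tied:
            return cid
    raise AssertionError("unreachable: tie set drawn from votes")


def per_cell_counts_3d(
    benchmark: Benchmark, labels: CellLabelMap
) -> tuple[list[CellProfile], int]:
    """Per-cell counts over a deduplicated stack.

    Each benchmark entry contributes one chloroplast to the cell chosen by
    majority vote over its history.  sum(per-cell counts) + background
    entries = benchmark count.
    """
    counts: Counter[int] = Counter()
    background = 0
    for entry in benchmark.entries:
        cid = _vote_cell(entry.history, labels)
        if cid == 0:
            background += 1
        else:
            counts[cid] += 1
    return _build_profiles(labels, dict(counts)), background


def border_cell_ids(labels: CellLabelMap) -> set[int]:
    """Ids of cells touching the raster border (for optional exclusion)."""
    d = labels.data
    edge = np.concatenate([d[0, :], d[-1, :], d[:, 0], d[:, -1]])
    return {int(i) for i in np.unique(edge) if i > 0}
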