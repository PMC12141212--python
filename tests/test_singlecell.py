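"""Per-cell attribution of detections and benchmark entries."""

import numpy as np
import pytest

from chlorocount import (
    Benchmark,
    Box,
    CellLabelMap,
    Detection,
    InvalidInputError,
    assign_cell,
    cell_areas,
    per_cell_counts_2d,
    per_cell_counts_3d,
)
from chlorocount.dedup import BenchmarkEntry
from chlorocount.singlecell import border_cell_ids, cell_centroids


@pytest.fixture
def two_cell_map():
    # left half cell 1, right half cell 2, one background column between
    arr = np.zeros((20, 41), dtype=np.int32)
    arr[:, :20] = 1
    arr[:, 21:] = 2
    return CellLabelMap(arr)


class TestAssignCell:
    def test_center_inside_cell(self, two_cell_map):
        assert assign_cell(Box(2, 2, 8, 8), two_cell_map) == 1
        assert assign_cell(Box(30, 2, 38, 8), two_cell_map) == 2

    def test_center_on_background(self, two_cell_map):
        assert assign_cell(Box(19, 2, 22, 8), two_cell_map) == 0

    def test_straddling_box_uses_center(self, two_cell_map):
        # box spans both cells; its center sits in cell 1
        assert assign_cell(Box(10, 2, 26, 8), two_cell_map) == 1

    def test_center_outside_raster_rejected(self, two_cell_map):
        with pytest.raises(InvalidInputError):
            assign_cell(Box(100, 2, 120, 8), two_cell_map)


class TestPerCell2D:
    def test_no_detections_gives_zero_profiles(self, two_cell_map):
        profiles, background = per_cell_counts_2d([], two_cell_map)
        assert [p.chloroplast_count for p in profiles] == [0, 0]
        assert background == 0

    def test_all_in_one_cell(self, two_cell_map):
        dets = [Detection(Box(2 + i, 2, 8 + i, 8)) for i in range(4)]
        profiles, background = per_cell_counts_2d(dets, two_cell_map)
        counts = {p.cell_id: p.chloroplast_count for p in profiles}
        assert counts == {1: 4, 2: 0}
        assert background == 0

    def test_partition_conservation(self, two_cell_map, rng):
        dets = []
        for _ in range(30):
            x0 = rng.uniform(0, 36)
            y0 = rng.uniform(0, 14)
            dets.append(Detection(Box(x0, y0, x0 + 4, y0 + 4)))
        profiles, background = per_cell_counts_2d(dets, two_cell_map)
        assert sum(p.chloroplast_count for p in profiles) + background == len(dets)


class TestPerCell3D:
    def _benchmark(self, histories):
        entries = [
            BenchmarkEntry(entry_id=i, history=h) for i, h in enumerate(histories)
        ]
        return Benchmark(tau=0.3, entries=entries)

    def test_majority_vote(self, two_cell_map):
        # votes: cell 2, cell 2, cell 2, background, background
        history = [
            (0, Box(30, 2, 38, 8), 1.0),
            (1, Box(31, 2, 39, 8), 1.0),
            (2, Box(30, 3, 38, 9), 1.0),
            (3, Box(19, 2, 22, 8), 1.0),
            (4, Box(18, 2, 23, 8), 1.0),
        ]
        profiles, background = per_cell_counts_3d(self._benchmark([history]), two_cell_map)
        counts = {p.cell_id: p.chloroplast_count for p in profiles}
        assert counts == {1: 0, 2: 1}
        assert background == 0

    def test_tie_breaks_to_earliest_slice(self, two_cell_map):
        history = [
            (0, Box(2, 2, 8, 8), 1.0),  # cell 1
            (1, Box(30, 2, 38, 8), 1.0),  # cell 2
        ]
        profiles, _bg = per_cell_counts_3d(self._benchmark([history]), two_cell_map)
        counts = {p.cell_id: p.chloroplast_count for p in profiles}
        assert counts == {1: 1, 2: 0}

    def test_partition_conservation(self, two_cell_map):
        histories = [
            [(0, Box(2, 2, 8, 8), 1.0)],
            [(0, Box(30, 2, 38, 8), 1.0)],
            [(0, Box(19, 2, 22, 8), 1.0)],  # background entry
        ]
        bm = self._benchmark(histories)
        profiles, background = per_cell_counts_3d(bm, two_cell_map)
        assert sum(p.chloroplast_count for p in profiles) + background == bm.count


class TestCellGeometry:
    def test_block_area(self):
        arr = np.zeros((10, 10), dtype=np.int32)
        arr[2:7, 3:8] = 3
        assert cell_areas(CellLabelMap(arr)) == {3: 25}

    def test_empty_map(self):
        assert cell_areas(CellLabelMap(np.zeros((5, 5), dtype=np.int32))) == {}

    def test_areas_partition_nonzero_pixels(self, two_cell_map):
        areas = cell_areas(two_cell_map)
        assert sum(areas.values()) == int(np.count_nonzero(two_cell_map.data))

    def test_centroid_of_block(self):
        arr = np.zeros((10, 10), dtype=np.int32)
        arr[2:7, 3:8] = 3  # rows 2..6, cols 3..7
        (cx, cy) = cell_centroids(CellLabelMap(arr))[3]
        assert (cx, cy) == (5.5, 4.5)

    def test_border_cells_found(self, two_cell_map):
        assert border_cell_ids(two_cell_map) == {1, 2}
        arr = np.zeros((10, 10), dtype=np.int32)
        arr[3:6, 3:6] = 4
        assert border_cell_ids(CellLabelMap(arr)) == set()


def test_end_to_end_per_cell_recovery(recovery_scene):
    """Simulated per-cell counts are recovered exactly in the low-jitter regime."""
    from chlorocount import count_stack, oracle_stack

    _spec, _stack, truth = recovery_scene
    _count, bm = count_stack(oracle_stack(truth), tau=0.3, min_confidence=0.5)
    profiles, background = per_cell_counts_3d(bm, truth.label_map)
    assert background == 0
    assert {p.cell_id: p.chloroplast_count for p in profiles} == truth.per_cell_counts
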