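"""Cross-slice deduplication: the benchmark accumulation rules."""

import pytest

from chlorocount import (
    Benchmark,
    Box,
    Detection,
    InvalidInputError,
    StackDetections,
    accumulate,
    count_stack,
    sweep_threshold,
)


def det(x0, y0, x1, y1, s=0, conf=1.0):
    return Detection(Box(x0, y0, x1, y1), conf, slice_index=s)


def stack_of(slices, size=200):
    return StackDetections(size, size, slices)


class TestAccumulate:
    def test_overlapping_box_merges(self):
        bm = Benchmark(tau=0.3)
        accumulate(bm, [det(0, 0, 10, 10, s=0)])
        accumulate(bm, [det(1, 0, 11, 10, s=1)])  # IOU = 90/110 > 0.3
        assert bm.count == 1
        assert bm.entries[0].current_box == Box(1, 0, 11, 10)
        assert (bm.entries[0].first_slice, bm.entries[0].last_slice) == (0, 1)

    def test_disjoint_box_founds_new_entry(self):
        bm = Benchmark(tau=0.3)
        accumulate(bm, [det(0, 0, 10, 10, s=0)])
        accumulate(bm, [det(30, 30, 40, 40, s=1)])
        assert bm.count == 2

    def test_identical_slices_of_disjoint_boxes(self):
        boxes = [(0, 0, 20, 20), (50, 0, 70, 20), (0, 50, 20, 70)]
        slices = [[det(*b, s=s) for b in boxes] for s in range(2)]
        count, _bm = count_stack(stack_of(slices), tau=0.3)
        assert count == 3

    def test_mixed_slice_indices_rejected(self):
        bm = Benchmark(tau=0.3)
        with pytest.raises(InvalidInputError):
            accumulate(bm, [det(0, 0, 10, 10, s=0), det(0, 0, 10, 10, s=1)])

    def test_merge_at_exact_tau_is_new_entry(self):
        # IOU exactly 1/3; merge requires IOU strictly above tau
        bm = Benchmark(tau=1 / 3)
        accumulate(bm, [det(0, 0, 10, 10, s=0)])
        accumulate(bm, [det(5, 0, 15, 10, s=1)])
        assert bm.count == 2

    def test_one_to_one_within_slice(self):
        # two same-slice detections may not collapse into one entry
        bm = Benchmark(tau=0.3)
        accumulate(bm, [det(0, 0, 10, 10, s=0)])
        accumulate(bm, [det(0, 0, 10, 10, s=1), det(1, 0, 11, 10, s=1)])
        assert bm.count == 2
        assert bm.total_observations == 3

    def test_best_iou_entry_wins(self):
        bm = Benchmark(tau=0.1)
        accumulate(bm, [det(0, 0, 10, 10, s=0), det(8, 0, 18, 10, s=0)])
        accumulate(bm, [det(7, 0, 17, 10, s=1)])  # closer to the second entry
        assert bm.count == 2
        assert bm.entries[1].current_box == Box(7, 0, 17, 10)

    def test_bridges_a_missed_slice(self):
        # entry persists across a slice where its chloroplast was not detected
        slices = [
            [det(0, 0, 10, 10, s=0)],
            [],
            [det(1, 0, 11, 10, s=2)],
        ]
        count, bm = count_stack(stack_of(slices), tau=0.3)
        assert count == 1
        assert bm.entries[0].n_observations == 2


class TestCountStack:
    def test_single_slice_needs_no_dedup(self):
        boxes = [(i * 30, 0, i * 30 + 20, 20) for i in range(7)]
        count, _ = count_stack(stack_of([[det(*b) for b in boxes]]), tau=0.3)
        assert count == 7

    def test_jittered_repeats_count_once(self):
        # 5 boxes of side 20 jittered by 1 px per slice: IOU ~ 0.9 >> 0.3
        count, bm = count_stack(
            stack_of(
                [
                    [det(x + s, 40 * i, x + s + 20, 40 * i + 20, s=s) for i, x in enumerate([0] * 5)]
                    for s in range(4)
                ]
            ),
            tau=0.3,
        )
        assert count == 5
        assert bm.total_observations == 20

    def test_disjoint_slices_add(self):
        s0 = [det(i * 30, 0, i * 30 + 20, 20, s=0) for i in range(3)]
        s1 = [det(i * 30, 100, i * 30 + 20, 120, s=1) for i in range(4)]
        count, _ = count_stack(stack_of([s0, s1]), tau=0.3)
        assert count == 7

    def test_empty_stack_counts_zero(self):
        count, bm = count_stack(stack_of([]), tau=0.3)
        assert count == 0 and bm.count == 0

    def test_confidence_filter_applies_before_dedup(self):
        slices = [[det(0, 0, 10, 10, s=0, conf=0.4), det(30, 0, 40, 10, s=0, conf=0.9)]]
        count, bm = count_stack(stack_of(slices), tau=0.3, min_confidence=0.5)
        assert count == 1
        assert bm.total_observations == 1

    def test_count_bounds(self, recovery_scene):
        from chlorocount import oracle_stack

        _spec, _stack, truth = recovery_scene
        st = oracle_stack(truth)
        count, bm = count_stack(st, tau=0.3, min_confidence=0.5)
        assert max(st.per_slice_counts()) <= count <= st.n_detections
        assert bm.total_observations == st.n_detections


class TestSweepThreshold:
    def test_counts_non_decreasing_in_tau(self, recovery_scene):
        from chlorocount import oracle_stack

        _spec, _stack, truth = recovery_scene
        taus = [i / 10 for i in range(10)]
        counts = [c for _t, c in sweep_threshold(oracle_stack(truth), taus)]
        assert counts == sorted(counts)

    def test_single_tau_reduces_to_count_stack(self, recovery_scene):
        from chlorocount import oracle_stack

        _spec, _stack, truth = recovery_scene
        st = oracle_stack(truth)
        [(tau, count)] = sweep_threshold(st, [0.3])
        assert (tau, count) == (0.3, count_stack(st, tau=0.3)[0])

    def test_counts_constant_where_ious_are_extreme(self):
        # cross-slice IOUs are either 0 or > 0.9, so any tau below 0.9 merges alike
        slices = [
            [det(40 * i, 0, 40 * i + 20, 20, s=s) for i in range(4)] for s in range(3)
        ]
        counts = [c for _t, c in sweep_threshold(stack_of(slices), [0.0, 0.3, 0.6, 0.85])]
        assert counts == [4, 4, 4, 4]

    def test_unsorted_taus_rejected(self):
        with pytest.raises(InvalidInputError):
            sweep_threshold(stack_of([]), [0.5, 0.3])
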