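"""Cross-slice deduplication of detections into a 3D count.

Chloroplasts appear in several adjacent focal planes of a z-stack, so summing
per-slice detections over-counts.  The remedy implemented here maintains a
*benchmark*: a running registry of distinct chloroplasts.  Slices are scanned
in focal order; each detection is compared by IOU against every entry already
in the benchmark.  If the best IOU strictly exceeds the threshold tau the
detection is absorbed by that entry (same chloroplast, seen again); otherwise
it founds a new entry.  The benchmark size after the last slice is the 3D
count.

Disambiguation when several detections and entries compete is greedy by
descending IOU with one-to-one assignment within a slice, so two detections
from the same slice can never collapse into one entry.  An entry's stored box
is replaced by the newest matched detection's box, which tolerates cumulative
lateral drift across focal adjustments.  Because matching runs against the
whole benchmark (not just the previous slice), an entry can bridge a slice in
which its chloroplast went undetected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .boxes import Box, Detection, StackDetections, iou
from .errors import InvalidInputError

__all__ = ["BenchmarkEntry", "Benchmark", "accumulate", "count_stack", "sweep_threshold"]

DEFAULT_TAU = 0.3
DEFAULT_MIN_CONFIDENCE = 0.5


@dataclass
class BenchmarkEntry:
    """One distinct chloroplast and the per-slice detections absorbed into it."""

    entry_id: int
    history: list[tuple[int, Box, float]]  # (slice_index, box, confidence), slice-ordered

    @property
    def current_box(self) -> Box:
        return self.history[-1][1]

    @property
    def first_slice(self) -> int:
        return self.history[0][0]

    @property
    def last_slice(self) -> int:
        return self.history[-1][0]

    @property
    def n_observations(self) -> int:
        return len(self.history)


@dataclass
class Benchmark:
    """The running registry of distinct chloroplasts."""

    tau: float = DEFAULT_TAU
    entries: list[BenchmarkEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau < 1.0):
            raise InvalidInputError(f"tau must lie in [0, 1), got {self.tau}")

    @property
    def count(self) -> int:
        return len(self.entries)

    @property
    def total_observations(self) -> int:
        return sum(e.n_observations for e in self.entries)

    def to_records(self) -> list[dict]:
        return [
            {
                "id": e.entry_id,
                "first_slice": e.first_slice,
                "last_slice": e.last_slice,
                "n_observations": e.n_observations,
                "boxes": [
                    {
                        "slice": s,
                        "x_min": b.x_min,
                        "y_min": b.y_min,
                        "x_max": b.x_max,
                        "y_max": b.y_max,
                        "confidence": c,
                    }
                    for (s, b, c) in e.history
                ],
            }
            for e in self.entries
        ]


def accumulate(benchmark: Benchmark, detections: list[Detection]) -> Benchmark:
    """Absorb one slice's detections into the benchmark.

    Every detection either extends the entry with which it shares the highest
    IOU strictly above ``benchmark.tau`` (one-to-one within the slice, greedy
    by descending IOU) or founds a new entry.  The entry count never
    decreases.  All detections must carry the same slice index.
    """
    if not detections:
        return benchmark
    slice_indices = {d.slice_index for d in detections}
    if len(slice_indices) != 1:
        raise InvalidInputError(
            f"accumulate expects one slice per call, got slice indices {sorted(slice_indices)}"
        )

    # candidate (detection, entry) pairs strictly above tau, best IOU first;
    # ties broken by detection order then entry id for determinism
    candidates: list[tuple[float, int, int]] = []
    for di, det in enumerate(detections):
        for ei, entry in enumerate(benchmark.entries):
            v = iou(det.box, entry.current_box)
            if v > benchmark.tau:
                candidates.append((v, di, ei))
    candidates.sort(key=lambda t: (-t[0], t[1], benchmark.entries[t[2]].entry_id))

    matched_det: dict[int, int] = {}
    used_entries: set[int] = set()
    for v, di, ei in candidates:
        if di in matched_det or ei in used_entries:
            continue
        matched_det[di] = ei
        used_entries.add(ei)

    next_id = max((e.entry_id for e in benchmark.entries), default=-1) + 1
    for di, det in enumerate(detections):
        obs = (det.slice_index, det.box, det.confidence)
        if di in matched_det:
            benchmark.entries[matched_det[di]].history.append(obs)
        else:
            benchmark.entries.append(BenchmarkEntry(entry_id=next_id, history=[obs]))
            next_id += 1
    return benchmark


def count_stack(
    stack: StackDetections,
    tau: float = DEFAULT_TAU,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> tuple[int, Benchmark]:
    """Deduplicate a whole stack and return the 3D count with its benchmark.

    Detections below ``min_confidence`` are dropped first.  The first slice's
    surviving detections seed the benchmark; later slices are absorbed in
    focal order.  An empty stack yields count 0.
    """
    if not (0.0 <= min_confidence <= 1.0):
        raise InvalidInputError(f"min_confidence must lie in [0, 1], got {min_confidence}")
    benchmark = Benchmark(tau=tau)
    n_processed = 0
    for dets in stack.slices:
        surviving = [d for d in dets if d.confidence >= min_confidence]
        n_processed += len(surviving)
        accumulate(benchmark, surviving)
    # conservation: every processed detection was absorbed by exactly one entry
    if benchmark.total_observations != n_processed:
        raise AssertionError(
            f"conservation violated: {benchmark.total_observations} observations "
            f"for {n_processed} processed detections"
        )
    return benchmark.count, benchmark


def sweep_threshold(
    stack: StackDetections,
    taus: list[float],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[tuple[float, int]]:
    """3D count as a function of tau — a diagnostic for threshold choice.

    Counts are non-decreasing in tau because the merge condition IOU > tau
    only gets stricter.
    """
    if any(not (0.0 <= t < 1.0) for t in taus):
        raise InvalidInputError("every tau must lie in [0, 1)")
    if list(taus) != sorted(taus):
        raise InvalidInputError("taus must be sorted ascending")
    return [(t, count_stack(stack, tau=t, min_confidence=min_confidence)[0]) for t in taus]
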