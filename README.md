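# chlorocount

Counting chloroplasts in a single microscope image undercounts badly: in a
thick plant cell most organelles lie away from any one focal plane, while
naively summing detections over a z-series counts every chloroplast once per
plane it appears in. `chlorocount` resolves this for anyone doing
quantitative plant cell biology with ordinary multi-focal light, fluorescence
or serial-section microscopy: it takes per-slice 2D detections from *any*
detector, removes cross-plane duplicates to produce a true 3D count,
attributes each counted chloroplast to a cell from an instance-segmentation
label map (e.g. Cellpose output), and summarizes cells as (area, chloroplast
count) points for morphological cell-type clustering.

## Method

**3D deduplication.** Detections are axis-aligned boxes. For boxes $A$, $B$,

$$\mathrm{IOU}(A,B) = \frac{|A \cap B|}{|A \cup B|} \in [0, 1],$$

0 for disjoint boxes, 1 for identical ones. Slices are scanned in focal
order while maintaining a *benchmark* — a registry of distinct chloroplasts.
Each detection is compared against every benchmark entry's latest box; if
the best IOU strictly exceeds a threshold $\tau$ (default 0.3) the detection
is absorbed by that entry, otherwise it founds a new entry. Competing
(detection, entry) pairs within a slice are resolved greedily by descending
IOU with one-to-one assignment. The benchmark size after the last slice is
the 3D count. Detections below a confidence floor (default 0.5) are ignored.

**Per-cell attribution.** A label map assigns each benchmark entry to the
cell under its box centers, by majority vote over the entry's history with
ties going to the earliest slice.

**Evaluation.** Standard detection metrics over one-to-one greedy matching
at $\mathrm{IOU} \ge 0.5$:

$$P = \frac{TP}{TP+FP},\quad R = \frac{TP}{TP+FN},\quad
F_1 = \frac{2\,TP}{2\,TP+FP+FN},\quad
AP = \int_0^1 P(R)\,dR,\quad mAP = \frac{1}{N}\sum_i AP_i,$$

with AP integrated exactly over the all-points-interpolated
precision envelope.

**Synthetic stacks.** A simulator renders z-stacks of Voronoi-partitioned
cells containing elliptical chloroplasts with z-dependent Gaussian defocus,
intensity attenuation, lateral jitter, and per-slice visibility — with full
ground truth (boxes, label map, per-cell counts), so the whole pipeline is
testable without any imaging data. A simple classical blob detector
(smooth → threshold → connected components → area filter) exercises the
image pathway; trained detectors plug in via YOLO-style text files.

## Worked example

```python
from chlorocount import (SceneSpec, generate_scene, oracle_stack,
                         count_stack, per_cell_counts_3d)

spec = SceneSpec(counts=(5, 8, 12, 20), jitter_px=0.5, seed=7)
stack, truth = generate_scene(spec)          # 5 slices, 4 cells, 45 chloroplasts
detections = oracle_stack(truth)             # ground-truth boxes as detections
count, benchmark = count_stack(detections, tau=0.3, min_confidence=0.5)
profiles, background = per_cell_counts_3d(benchmark, truth.label_map)

print("per-slice detections:", detections.per_slice_counts())
print("3D count:", count)
for p in profiles:
    print(f"cell {p.cell_id}: area {p.area_px} px^2, {p.chloroplast_count} chloroplasts")
```

prints

```
per-slice detections: [14, 23, 25, 25, 11]
3D count: 45
cell 1: area 28986 px^2, 5 chloroplasts
cell 2: area 22805 px^2, 8 chloroplasts
cell 3: area 17402 px^2, 12 chloroplasts
cell 4: area 25671 px^2, 20 chloroplasts
```

No single slice sees more than 25 of the 45 chloroplasts, and the five
slices together yield 98 raw detections; the IOU deduplication recovers
exactly the 45 simulated organelles and their exact per-cell split. The
same flow runs from the shell:

```bash
chlorocount simulate --out scene/ --seed 7
chlorocount detect --images scene/ --out pred/ --fixed-threshold 0.15
chlorocount count3d --pred pred/ --width 320 --height 320 --out report/
chlorocount percell --pred pred/ --labels scene/labels.tif --k 2 --out cells/
chlorocount eval --pred pred/ --truth scene/ --width 320 --height 320
```

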