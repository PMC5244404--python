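# clecount

Automated cell counting for probe-based confocal laser endomicroscopy
(pCLE) video, with the validation and group-comparison statistics that
go with it, and a seeded synthetic-video generator that makes the whole
chain testable without animal data.

**Who it is for.** Labs that image fluorescently labeled cells (e.g.
dye-labeled mesenchymal stem cells delivered to the lung) through a
fiber-optic endomicroscope and need per-frame cell counts, per-video
and per-animal summaries, agreement against manual counts, and
nonparametric comparisons between delivery routes or treatment arms.
Cells appear as bright, roughly circular spots inside a circular field
of view; probe and respiratory motion make them enter and leave the
field, so frames are counted independently — no cross-frame tracking.

## The algorithm

For each frame, with every level defined relative to the frame's own
intensity distribution (gain-invariant):

1. **Contrast stretch** — linear percentile stretch onto [0, 1]
   (defaults: 1.0 / 99.8th percentiles of in-FOV pixels).
2. **Granulometry** (once per video) — open with disks of increasing
   radius r and record total in-FOV intensity S(r); the pattern
   spectrum −ΔS(r) peaks at the dominant spot radius, which calibrates
   the structuring element.
3. **Opening** — grayscale opening with a disk just below the spot
   size removes speckle and debris while cells survive.
4. **Double threshold** — hysteresis segmentation: keep pixels above
   the low quantile L only if connected to a seed above the high
   quantile H (defaults: 0.997 / 1.0 of the opened image).
5. **Connected components** — count components that pass an area band
   and a circularity floor C = 4πA/P² ≥ 0.4.

Counts aggregate to per-video means/totals and per-rat summaries.
Agreement between automatic and manual counts uses **Lin's concordance
correlation coefficient** ρc = 2σxy / (σx² + σy² + (μx − μy)²); group
differences use the **Mann-Whitney U test**, exact by full enumeration
for tie-free designs up to pooled n = 12 (a 5-vs-5 animal study is
always exact), normal approximation with tie correction otherwise.

## Worked example

Simulate a short video (24 frames, 512×512, on average 3.6 visible
cells per frame at SNR 10), calibrate the structuring element from its
granulometry, and count:

```sh
$ clecount --quiet simulate --out demo --seed 7 --n-frames 24 --frame-size 512
wrote demo/video.tif (24 frames)

$ clecount --quiet calibrate demo/video.tif --max-radius 10 --frames 24 --out detect.toml
granulometry peak 4 px -> se_radius 2; wrote detect.toml

$ clecount --quiet count demo/video.tif --config detect.toml --out counts.csv
24 frames, mean count 1.708, total 41; wrote counts.csv
```

The calibration found the modal pattern-spectrum peak at 4 px — the
granulometric size of nominal radius-5 Gaussian spots — and set the
opening radius two below it. The video's ground truth
(`demo/truth.csv`) holds a mean true count of 1.667 cells/frame for
this seed; the pipeline reports 1.708, the difference being one
borderline frame. `counts.csv` lists one row per detected object
(centroid, area, perimeter, circularity, mean intensity) plus the
per-frame count; every run writes a JSON manifest with the resolved
parameters and seeds.

Downstream, `clecount validate` computes CCC between automatic and
manual counts (and observer vs. observer), and `clecount compare`
runs the exact Mann-Whitney comparison between two groups of videos at
the animal or video level.

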