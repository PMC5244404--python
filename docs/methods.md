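# Methods

`clecount` counts fluorescently labeled cells in probe-based confocal
laser endomicroscopy (pCLE) video. Labeled cells appear as bright,
roughly circular spots of a characteristic size inside a circular
fiber-bundle field of view (FOV); the tissue contributes a textured
autofluorescence background, and probe and respiratory motion make
cells enter and leave the field between frames. Because individual
cells cannot be tracked through that motion, every frame is treated as
a stand-alone image and the scientific quantities are per-frame counts
and their per-video / per-animal aggregates.

## The counting pipeline

Each frame passes through five deterministic stages. All levels are
defined relative to percentiles or quantiles of in-FOV intensities, so
the pipeline is invariant to multiplication of the raw data by any
positive constant (detector gain).

1. **Contrast stretch.** Linear percentile stretch onto [0, 1]:
   intensities at or below the `enhance_low_pct` percentile (default
   1.0) map to 0, at or above `enhance_high_pct` (default 99.8) map
   to 1. The high percentile is deliberately placed so that *every*
   cell saturates at exactly 1.0 while almost all background does not;
   the saturation ties are exploited by the threshold stage below.
2. **Size calibration (once per video, not per frame).**
   Granulometry: the image is opened with disks of increasing radius
   and the total in-FOV intensity recorded; the negative first
   difference of that curve (the pattern spectrum) peaks at the
   dominant bright-structure radius. Losses are attributed to the
   largest radius the vanished structure still survived, so a filled
   disk of radius r peaks at r exactly, and sub-structuring-element
   speckle lands in bin 0, which never wins the peak. Because cells
   occupy well under 1% of the FOV, a raw-frame pattern spectrum is
   dominated by background texture; calibration therefore smooths
   (Gaussian, sigma 2.5 px) and binarizes each frame at
   median + 3 x 1.4826 x MAD of in-FOV intensities before the
   spectrum is computed. Median/MAD track the background level and
   spread regardless of how many cells a frame holds, which a fixed
   quantile cannot do; both are scale-free. Noise-free frames skip
   the smoothing (it would shrink clean compact objects) and are cut
   at half range. The calibrated radius is the modal per-frame peak,
   ties broken toward the smaller radius; a video with no usable peak
   raises a calibration error instructing the user to set `se_radius`
   by hand.
3. **Opening.** Grayscale morphological opening with a disk of radius
   `se_radius`, set two pixels below the granulometric peak (floor 1).
   With Gaussian-profile spots the pattern-spectrum peak sits at about
   0.85x the nominal spot radius and the saturated plateau that must
   survive the opening at about 0.6x, so opening one below the peak —
   the first choice considered — clips the plateau of smaller cells
   (measured recall 0.88–0.93 versus ~1.0 at peak minus two). The
   opening flattens everything that cannot contain the disk:
   sub-cellular speckle, debris and most background texture.
4. **Hysteresis (double) threshold.** Absolute levels L and H are the
   `thr_low` and `thr_high` quantiles (defaults 0.997 and 1.0) of the
   opened image's in-FOV intensities; a pixel is foreground iff it is
   >= L and 8-connected to a pixel >= H. `thr_high = 1.0` makes the
   seed level the in-FOV *maximum*: every saturated cell plateau wider
   than the opening disk survives the opening at exactly 1.0, so on
   cell-rich frames all cells seed (no competition for a fixed top
   quantile), while on sparse frames the background — which never
   reaches 1.0 — cannot seed. Degenerate levels (L = H, e.g. a
   constant frame) reduce to a single threshold; the resulting
   whole-field component is removed by the area filter.
5. **Connected components with shape filters.** 8-connected components
   are kept if their area lies in `[min_area, max_area]` (defaults
   0.4x and 8x the nominal spot disk area pi (se_radius + 2)^2) and
   their circularity 4 pi A / P^2 (perimeter by the weighted
   boundary-step estimate, diagonals sqrt 2) is at least 0.4. The area
   floor removes residual background plateaus the size of the
   structuring element; the ceiling removes merged clumps and the
   degenerate whole-field component; the circularity floor removes
   elongated debris and streaks.

An alternative `tophat` switch thresholds a granulometric band-pass
(opening at `se_radius` minus opening at `se_radius + 4`; the FOV is
eroded by the larger radius because the residue is undefined near the
rim). Differencing the raw stretched image instead re-admits the
speckle the opening exists to remove and is noise-dominated at
SNR 10. Even as a band-pass the mode trades recall for background
suppression (~0.6 versus ~1.0 on the same frames) and is secondary;
the default opening path is recommended.

### Choosing the percentile defaults

Neither the threshold levels nor the structuring-element radius of the
original workflow are recoverable from published material, so the
shipped defaults were fixed once against the synthetic benchmark at
the default study geometry (512 x 512 frames, 3.6 cells/frame,
SNR 10): precision 0.986 and recall 0.999 over 200 frames. Two
defaults are geometry-dependent and must be re-resolved when the field
or the cell density changes substantially: `enhance_high_pct` and
`thr_low` both encode an expected *foreground fraction* (about 0.2–0.3%
of the FOV at the default geometry). On a 128 x 128 field the same
cells cover ~3% of the FOV, and the evaluation harness accordingly uses
`enhance_high_pct = 97.0`, `thr_low = 0.95` there. This is the honest
cost of the scale-free quantile contract: levels are relative to each
frame's own intensity distribution, so they embed an assumption about
how much of the frame is signal.

### Known limitation: sparse and empty frames

With quantile-relative levels an empty frame still has a maximum, and
its surrounding cluster occasionally passes the shape filters: about
0.8 false positives per empty frame at default settings. At the
default rate of 3.6 cells/frame (2.7% empty frames) this costs ~1% in
precision; on videos that are mostly empty (e.g. 0.5 cells/frame) the
per-frame mean is inflated by roughly +0.5 to +0.8. Group comparisons
are insensitive to this (the offset is common to both groups and the
rank test uses ordering only), but absolute counts from very sparse
videos should be read with that bias in mind.

## Validation statistics

**Lin's concordance correlation coefficient** measures agreement
between two count series (automatic vs. manual, observer vs.
observer): rho_c = 2 s_xy / (s_x^2 + s_y^2 + (m_x - m_y)^2) with
population (1/n) moments. Unlike Pearson's r it penalizes location
and scale shifts; rho_c = 1 only for exact agreement. Two identical
constant series are defined to agree perfectly (rho_c = 1), two
different constant ones not at all (rho_c = 0). Manual ground truth
averaged over two observers may be half-integer; all statistics accept
non-integer values.

**Mann-Whitney U** compares two groups of per-unit summaries. For
tie-free pooled samples of at most 12 the two-sided p-value is exact:
P(|U - n_a n_b / 2| >= observed) over all C(n_a + n_b, n_a)
assignments, capped at 1 — so a 5-vs-5 animal design is always exact.
Larger or tied samples use the normal approximation with tie-corrected
variance and a 0.5 continuity correction; every result records which
method produced it. The statistical unit defaults to the animal (each
rat contributes the mean of its videos' statistic, matching a design
with two consecutive acquisitions per animal); per-video comparisons
are also supported and the unit is always recorded.

## The synthetic video generator

The generator emulates exactly the image features the counting
algorithm is sensitive to, with one integer seed controlling three
independent RNG streams (cells, debris, background) so that, e.g.,
changing the debris density leaves the cell realization untouched.

- **Geometry:** 512 x 512 frames, circular FOV at 0.45 of the short
  edge, 240 frames per video standing in for a ~2-minute acquisition.
- **Cells:** isotropic Gaussian spots, sigma = radius / 2 (nominal
  radius 5.0 +- 0.5 px, truncated at +-3 sd), peak amplitude
  `cell_peak_snr` (default 10) times the background noise sd, jittered
  +-10%. Centroids are placed uniformly in the FOV with the whole
  spot inside — ground truth counts whole visible cells, as a manual
  observer would.
- **Dynamics:** per-cell Bernoulli persistence (default 0.8 per frame)
  plus Poisson births at rate cell_rate x (1 - persistence), started
  at stationarity, so the expected visible count is `cell_rate`
  (default 3.6) in every frame. This reproduces appearance and
  disappearance under probe/respiratory motion without modeling
  within-field drift, to which a per-frame counter is blind.
- **Debris:** sub-resolution bright specks (radius <= 1 px) at 10 per
  frame, redrawn every frame, amplitudes comparable to cells.
- **Background:** constant offset (20) plus white noise smoothed at a
  1.5 px texture scale and rescaled to sd 2.0 — fine-grained
  autofluorescence mottle.
- **Not modeled:** the fiber-bundle honeycomb, within-FOV motion blur,
  photobleaching, physiological breathing kernels, and large-scale
  tissue autofluorescence structure. Passing tests therefore show
  that the chain recovers known truth under controlled conditions, not
  that it is robust to every artifact of real endomicroscopy video;
  the agreement statistics against manual counts exist precisely for
  the real-data case.

Simulated studies assign each rat to one (condition, route) arm and
spawn one child seed per video from the master seed, so any video can
be regenerated in isolation.

## Evaluation harness

`clecount.evaluation` (driven by `scripts/acceptance.py` and the
acceptance tests) re-derives the package's headline numbers from
scratch at these problem sizes, chosen to exercise each claim at
desk scale:

- CCC vs. an independent Pearson-form oracle on 1,000 random count
  pairs; exact Mann-Whitney vs. full enumeration with direct pairwise
  counting for every tie-free design with pooled n <= 10.
- Granulometric peak on constructed disk images (radii 3–9, exact) and
  per-frame calibration on 100 simulated 256 x 256 fields with nominal
  radii 4–6 (hit = within 1 px).
- Detection precision/recall over 200 default-geometry frames, with a
  paired debris-free rerun (debris must change no frame's count).
- Count-rate recovery over one 240-frame video: the mean detected
  count must lie within the 99% confidence interval of the mean true
  count.
- Study-level power (rates 3.6 vs 0.5, 5 rats x 2 videos, 100
  replicates) and type-I error (equal rates, 200 replicates) of the
  full simulate-count-compare chain at the reduced 128 x 128 geometry
  with 24 frames per video.
- Byte-identity of two runs of the file-level pipeline.

## Numerical choices

- Discrete disks of successive radii are not perfectly open with
  respect to one another; the granulometry curve is forced
  non-increasing by a running minimum (sub-pixel-mass corrections).
- Circularity is clamped to [0, 1]; a single-pixel component (zero
  perimeter) is treated as perfectly round and in practice removed by
  the area floor.
- Greedy distance-ordered one-to-one matching scores detections
  against truth; a detection landing on debris counts as a false
  positive.
- Quantiles use NumPy's default linear interpolation; ties at the
  saturated value 1.0 are exact by construction (clipping).
- Mode ties in calibration and group-label ordering both break
  deterministically (smaller radius; alphabetical level).
- Outputs are written atomically (temp file + rename); a failed run
  leaves no partial CSV/TIFF behind.
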