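"""Per-frame spot detection for endomicroscopy video.

Fluorescently labeled cells appear as bright, roughly circular spots on
a textured autofluorescence background.  Each frame is processed as a
stand-alone image through the classic morphological chain:

1. linear percentile contrast stretch (scale-free),
2. granulometry with disk structuring elements to calibrate the
   dominant spot radius (done once per video, not per frame),
3. grayscale opening with a disk slightly smaller than the spots, which
   flattens sub-cellular speckle while leaving the spots intact,
4. hysteresis (double) threshold at quantile-relative levels,
5. connected-component labeling with an area band and a circularity
   floor to reject debris and elongated artifacts.

Counts are per frame; no identity is propagated between frames.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .core import Frame
from .params import DetectionParams

logger = logging.getLogger(__name__)

#: Preprocessing constants for granulometric size calibration.  The
#: calibration frames are smoothed, then binarized at a robust
#: background-relative level (median + CALIBRATION_MAD_K scaled-MAD of
#: in-FOV intensities) before the pattern spectrum is computed.  Cells
#: occupy well under 1% of the field of view, so median/MAD track the
#: background regardless of how many cells a frame holds — a fixed
#: quantile cannot, because the level a given quantile lands on moves
#: with the per-frame cell count.  Both steps are invariant to positive
#: rescaling of the raw intensities.
CALIBRATION_SMOOTH_SIGMA = 2.5
CALIBRATION_MAD_K = 3.0


class CalibrationError(RuntimeError):
    """Raised when no frame yields a usable granulometric size peak."""


@dataclass
class GranulometryProfile:
    """Granulometry curve and pattern spectrum of one frame.

    ``surface_area[r]`` is the total in-FOV intensity after opening with
    a disk of radius ``radii[r]``; the pattern spectrum is its negative
    first difference.  ``pattern_spectrum[r]`` attributes each loss to
    the largest radius the vanished structure still survived: it is the
    intensity of structures of granulometric size exactly ``r`` (kept by
    the radius-``r`` disk, erased by radius ``r + 1``), so a filled
    Euclidean disk of radius ``r`` peaks at ``r``, not at the step that
    removed it.  ``peak_radius`` is the argmax over positive radii;
    entry 0 (sub-structuring-element speckle) never wins the peak.
    """

    radii: np.ndarray
    surface_area: np.ndarray
    pattern_spectrum: np.ndarray
    peak_radius: int | None

    @property
    def has_peak(self) -> bool:
        return self.peak_radius is not None


@dataclass(frozen=True)
class DetectedObject:
    """One connected component that survived the size and shape filters."""

    centroid_row: float
    centroid_col: float
    area: int
    perimeter: float
    circularity: float
    mean_intensity: float


@dataclass
class FrameDetection:
    """Detections of one frame; ``count == len(objects)`` always."""

    frame_index: int
    objects: list[DetectedObject] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.objects)


def enhance_contrast(frame: Frame, low_pct: float = 1.0, high_pct: float = 99.5) -> Frame:
    """Linear percentile stretch of in-FOV intensities onto [0, 1].

    Intensities at or below the ``low_pct`` percentile map to 0, at or
    above ``high_pct`` to 1, linearly in between.  Percentiles are
    computed over in-FOV pixels only, making the stretch invariant to
    multiplication of the raw intensities by any positive constant.
    Pixels outside the FOV are set to 0.
    """
    if not low_pct < high_pct:
        raise ValueError(f"require low_pct < high_pct, got {low_pct} / {high_pct}")
    fov = frame.resolved_fov()
    vals = frame.pixels[fov]
    lo, hi = np.percentile(vals, [low_pct, high_pct])
    out = np.zeros_like(frame.pixels)
    if hi <= lo:
        logger.warning(
            "constant image within percentile window (%.6g == %.6g); returning all-zero frame",
            lo,
            hi,
        )
        return frame.with_pixels(out)
    np.clip((frame.pixels - lo) / (hi - lo), 0.0, 1.0, out=out)
    out[~fov] = 0.0
    return frame.with_pixels(out)


def _disk(radius: int) -> np.ndarray:
    return morphology.disk(radius)


def open_frame(frame: Frame, se_radius: int) -> Frame:
    """Grayscale morphological opening with a disk structuring element.

    Anti-extensive (output <= input pixelwise) and idempotent; removes
    bright structure that cannot contain the disk.
    """
    if se_radius < 1:
        raise ValueError(f"se_radius must be >= 1, got {se_radius}")
    opened = ndimage.grey_opening(frame.pixels, footprint=_disk(se_radius), mode="nearest")
    return frame.with_pixels(opened)


def compute_granulometry(frame: Frame, max_radius: int) -> GranulometryProfile:
    """Granulometry of a (contrast-enhanced) frame with disks of radius 0..max_radius.

    The surface-area curve is forced non-increasing by a running
    minimum: discrete disks of successive radii are not perfectly
    open with respect to each other, which can otherwise leave
    sub-pixel-mass inversions in the curve.
    """
    h, w = frame.pixels.shape
    if not (1 <= max_radius < min(h, w) / 2):
        raise ValueError(
            f"max_radius must satisfy 1 <= max_radius < {min(h, w) / 2}, got {max_radius}"
        )
    fov = frame.resolved_fov()
    # open one radius past max_radius so the last size bin is closed
    radii = np.arange(max_radius + 2)
    surface = np.empty(max_radius + 2)
    surface[0] = frame.pixels[fov].sum()
    for r in range(1, max_radius + 2):
        opened = ndimage.grey_opening(frame.pixels, footprint=_disk(r), mode="nearest")
        surface[r] = min(opened[fov].sum(), surface[r - 1])
    # spectrum[r]: mass surviving opening at r but not at r + 1
    spectrum = surface[:-1] - surface[1:]
    positive_part = spectrum[1:]
    if np.all(positive_part <= 0):
        peak: int | None = None
    else:
        peak = int(1 + np.argmax(positive_part))
    return GranulometryProfile(
        radii=radii,
        surface_area=surface,
        pattern_spectrum=spectrum,
        peak_radius=peak,
    )


def calibration_enhance(
    frame: Frame,
    smooth_sigma: float = CALIBRATION_SMOOTH_SIGMA,
    mad_k: float = CALIBRATION_MAD_K,
) -> Frame | None:
    """Extreme contrast stretch used for size calibration.

    Smooths the frame, then maps everything at or below a robust
    background ceiling (median + ``mad_k`` scaled-MAD of in-FOV
    intensities) to 0 and everything above it to 1, i.e. a binarizing
    stretch.  Noise-free frames (raw MAD = 0) skip the smoothing — it
    exists only to suppress noise, and would shrink clean compact
    objects — and are cut halfway between the median and the maximum.
    Returns ``None`` for constant frames, which carry no size
    information.
    """
    fov = frame.resolved_fov()
    raw = frame.pixels[fov]
    raw_med = float(np.median(raw))
    raw_mad = float(np.median(np.abs(raw - raw_med)))
    if raw_mad > 0:
        sm = ndimage.gaussian_filter(frame.pixels, smooth_sigma)
        vals = sm[fov]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        if mad == 0:  # smoothing flattened everything
            return None
        cut = med + mad_k * 1.4826 * mad
    else:
        sm = frame.pixels
        vmax = float(raw.max())
        if vmax <= raw_med:
            return None
        cut = raw_med + 0.5 * (vmax - raw_med)
    binary = ((sm >= cut) & fov).astype(np.float64)
    return frame.with_pixels(binary)


def calibrate_se_radius(
    frames: list[Frame],
    max_radius: int,
    smooth_sigma: float = CALIBRATION_SMOOTH_SIGMA,
    mad_k: float = CALIBRATION_MAD_K,
) -> int:
    """Modal granulometric peak radius over calibration frames.

    Each frame passes through :func:`calibration_enhance` before its
    pattern spectrum is computed; frames with no peak (constant or empty
    fields) are excluded.  Ties in the mode break toward the smaller
    radius.
    """
    if not frames:
        raise ValueError("need at least one calibration frame")
    peaks = []
    for f in frames:
        enhanced = calibration_enhance(f, smooth_sigma, mad_k)
        if enhanced is None:
            continue
        prof = compute_granulometry(enhanced, max_radius)
        if prof.has_peak:
            peaks.append(prof.peak_radius)
    if not peaks:
        raise CalibrationError(
            "no calibration frame produced a granulometric size peak; "
            "supply se_radius manually"
        )
    counts = Counter(peaks)
    top = max(counts.values())
    return min(r for r, c in counts.items() if c == top)


def _label(mask: np.ndarray, connectivity: int) -> np.ndarray:
    # skimage connectivity: 1 = 4-neighborhood, 2 = 8-neighborhood
    return measure.label(mask, connectivity=1 if connectivity == 4 else 2)


def double_threshold(
    frame: Frame,
    thr_low: float,
    thr_high: float,
    connectivity: int = 8,
) -> np.ndarray:
    """Hysteresis threshold at quantile-relative levels.

    Absolute levels ``L = quantile(thr_low)`` and ``H =
    quantile(thr_high)`` are taken over in-FOV pixels; a pixel is
    foreground iff it is >= L and connected (at the given connectivity)
    to some pixel >= H.  Degenerate quantiles (L == H) reduce to a
    single threshold at H.  The mask is false outside the FOV.
    """
    if not thr_low <= thr_high:
        raise ValueError(f"require thr_low <= thr_high, got {thr_low} / {thr_high}")
    fov = frame.resolved_fov()
    vals = frame.pixels[fov]
    L, H = np.quantile(vals, [thr_low, thr_high])
    if L >= H:
        logger.info("degenerate hysteresis levels (L == H == %.6g); single threshold", H)
        return (frame.pixels >= H) & fov
    low_mask = (frame.pixels >= L) & fov
    labels = _label(low_mask, connectivity)
    seeds = labels[(frame.pixels >= H) & fov]
    keep = np.zeros(labels.max() + 1, dtype=bool)
    keep[np.unique(seeds)] = True
    keep[0] = False
    return keep[labels]


def _circularity(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0  # single pixel; treated as perfectly round
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def label_and_filter(
    mask: np.ndarray,
    enhanced: Frame,
    params: DetectionParams,
    frame_index: int | None = None,
) -> FrameDetection:
    """Connected-component labeling with area, shape and FOV filters.

    Components with area outside ``[min_area, max_area]``, circularity
    (4*pi*A/P**2, perimeter by the weighted boundary-step estimate,
    diagonal steps weighted sqrt(2)) below ``min_circularity``, or any
    pixel outside the FOV are discarded.
    """
    if mask.shape != enhanced.pixels.shape:
        raise ValueError("mask and frame shapes differ")
    fov = enhanced.resolved_fov()
    labels = _label(mask, params.connectivity)
    idx = frame_index if frame_index is not None else enhanced.frame_index
    objects: list[DetectedObject] = []
    for region in measure.regionprops(labels, intensity_image=enhanced.pixels):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        circ = _circularity(region.area, region.perimeter)
        if circ < params.min_circularity:
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        if not fov[rr, cc].all():
            continue
        r0, c0 = region.centroid
        objects.append(
            DetectedObject(
                centroid_row=float(r0),
                centroid_col=float(c0),
                area=int(region.area),
                perimeter=float(region.perimeter),
                circularity=circ,
                mean_intensity=float(region.intensity_mean),
            )
        )
    return FrameDetection(frame_index=idx, objects=objects)


def detection_mask(frame: Frame, params: DetectionParams) -> tuple[np.ndarray, Frame]:
    """Binary foreground mask and the enhanced frame it was derived from.

    Runs the pipeline up to (and including) the hysteresis threshold;
    :func:`count_frame` adds the connected-component filtering on top.
    """
    enhanced = enhance_contrast(frame, params.enhance_low_pct, params.enhance_high_pct)
    if params.tophat:
        # top-hat-style background suppression, taken between openings
        # at the calibrated size and a few pixels above the widest
        # saturated cell footprint: a granulometric band-pass.
        # Differencing the raw enhanced image instead would re-admit
        # all the sub-cellular speckle the opening exists to remove.
        big = params.se_radius + 4
        opened_small = open_frame(enhanced, params.se_radius)
        opened_big = open_frame(enhanced, big)
        # the residue is undefined within one structuring element of the
        # FOV rim (the opening bites into the dark surround there), so
        # that ring is excluded from the working field of view
        fov = ndimage.binary_erosion(enhanced.resolved_fov(), structure=_disk(big))
        work = Frame(
            np.clip(opened_small.pixels - opened_big.pixels, 0.0, None) * fov,
            fov_mask=fov,
            frame_index=frame.frame_index,
        )
        enhanced = Frame(enhanced.pixels, fov_mask=fov, frame_index=frame.frame_index)
    else:
        work = open_frame(enhanced, params.se_radius)
    mask = double_threshold(work, params.thr_low, params.thr_high, params.connectivity)
    return mask, enhanced


def count_frame(frame: Frame, params: DetectionParams) -> FrameDetection:
    """Full per-frame pipeline: stretch, open, double-threshold, label, filter.

    Deterministic: identical inputs give identical outputs.  With
    ``params.tophat`` the hysteresis threshold is applied to a
    granulometric band-pass (opening at ``se_radius`` minus opening at
    ``se_radius + 4``) rather than to the opening itself.
    """
    mask, enhanced = detection_mask(frame, params)
    return label_and_filter(mask, enhanced, params, frame_index=frame.frame_index)
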