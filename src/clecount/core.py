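"""Core containers for endomicroscopy frames.

A probe-based confocal laser endomicroscope images a circular field of
view (FOV) through a fiber bundle; pixels outside that circle carry no
signal.  Every frame therefore pairs a grayscale intensity image with an
optional boolean FOV mask.  Frames are treated as independent,
stand-alone images throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def estimate_fov_mask(shape: tuple[int, int]) -> np.ndarray:
    """Largest inscribed circle centred on the image.

    Used when no explicit FOV mask accompanies a frame; the fiber face is
    assumed centred with its rim touching the shorter image edge.
    """
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError(f"empty image shape {shape!r}")
    radius = min(h, w) / 2.0
    rr, cc = np.ogrid[:h, :w]
    cr, cw = (h - 1) / 2.0, (w - 1) / 2.0
    return (rr - cr) ** 2 + (cc - cw) ** 2 <= radius**2


def circular_mask(
    shape: tuple[int, int], radius: float, center: tuple[float, float] | None = None
) -> np.ndarray:
    """Boolean disk of the given radius (pixels) inside ``shape``."""
    h, w = shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    rr, cc = np.ogrid[:h, :w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@dataclass
class Frame:
    """One grayscale endomicroscopy frame.

    Parameters
    ----------
    pixels
        2-D array of nonnegative intensities, arbitrary units.
    fov_mask
        Optional boolean array of the same shape; ``True`` marks pixels
        inside the circular field of view.  When absent, operations that
        need a mask estimate the largest inscribed circle.
    frame_index
        Nonnegative position of the frame within its video.
    """

    pixels: np.ndarray
    fov_mask: np.ndarray | None = None
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be nonnegative")
        if self.fov_mask is not None:
            self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
            if self.fov_mask.shape != self.pixels.shape:
                raise ValueError(
                    f"fov_mask shape {self.fov_mask.shape} does not match "
                    f"pixels shape {self.pixels.shape}"
                )
        if self.frame_index < 0:
            raise ValueError("frame_index must be nonnegative")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def resolved_fov(self) -> np.ndarray:
        """The FOV mask, estimating an inscribed circle if none was given."""
        if self.fov_mask is not None:
            return self.fov_mask
        return estimate_fov_mask(self.pixels.shape)

    def with_pixels(self, pixels: np.ndarray) -> "Frame":
        """Copy of this frame carrying new pixel values."""
        return Frame(pixels=pixels, fov_mask=self.fov_mask, frame_index=self.frame_index)
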