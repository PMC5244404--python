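"""Detection parameters and flat key-value configuration files.

All tunables of the per-frame counting algorithm live in
:class:`DetectionParams`.  Configurations are stored as flat TOML
(``key = value`` per line) so a run is fully described by one small
text file; every CLI run echoes the resolved set.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, asdict
from pathlib import Path


def derived_area_band(se_radius: int) -> tuple[int, int]:
    """Default object-area band (pixels) implied by the opening radius.

    The opening radius sits two pixels below the nominal spot radius
    (granulometric peak = spot radius - 1, opening radius = peak - 1),
    so the nominal spot radius is ``se_radius + 2``.  The lower bound
    (40% of the nominal spot disk area) rejects residual background
    plateaus and speckle; the upper bound (8x the spot disk) passes
    merged pairs but rejects large background patches and the degenerate
    whole-field component.
    """
    spot_radius = se_radius + 2
    min_area = math.ceil(0.4 * math.pi * spot_radius**2)
    max_area = math.ceil(8.0 * math.pi * spot_radius**2)
    return min_area, max_area


@dataclass(frozen=True)
class DetectionParams:
    """Tunables of the counting algorithm.

    Attributes
    ----------
    enhance_low_pct, enhance_high_pct
        Percentiles (of in-FOV intensities) mapped to 0 and 1 by the
        linear contrast stretch; both in [0, 100) with low < high.
    se_radius
        Disk structuring-element radius (pixels) for the grayscale
        opening; typically the granulometry peak radius minus two so
        the saturated core of every cell survives while finer speckle
        is flattened.
    thr_low, thr_high
        Quantile levels in (0, 1] of the opened image's in-FOV
        intensities defining the hysteresis (double) threshold.  The
        default ``thr_high = 1.0`` places the seed level at the in-FOV
        maximum: the contrast stretch saturates every cell at exactly
        1.0, and saturated plateaus wider than the opening disk survive
        the opening at 1.0, so every cell seeds while quantile creep on
        sparse frames cannot promote background.
    min_area, max_area
        Connected-component area band in pixels.
    min_circularity
        Floor on 4*pi*A/P**2; rejects elongated debris and streaks.
    connectivity
        Pixel connectivity for hysteresis and labeling: 4 or 8.
    tophat
        When true, threshold a granulometric band-pass (opening at
        ``se_radius`` minus opening at ``se_radius + 4``) instead of
        the opening itself; stronger background suppression at a
        measurable cost in recall — see docs/methods.md.
    """

    se_radius: int
    enhance_low_pct: float = 1.0
    enhance_high_pct: float = 99.8
    thr_low: float = 0.997
    thr_high: float = 1.0
    min_area: int = 0  # 0 -> derive from se_radius in __post_init__
    max_area: int = 0
    min_circularity: float = 0.4
    connectivity: int = 8
    tophat: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.enhance_low_pct < self.enhance_high_pct < 100):
            raise ValueError(
                "require 0 <= enhance_low_pct < enhance_high_pct < 100, got "
                f"{self.enhance_low_pct} / {self.enhance_high_pct}"
            )
        if int(self.se_radius) != self.se_radius or self.se_radius < 1:
            raise ValueError(f"se_radius must be a positive integer, got {self.se_radius}")
        object.__setattr__(self, "se_radius", int(self.se_radius))
        if not (0 < self.thr_low <= self.thr_high <= 1):
            raise ValueError(
                f"require 0 < thr_low <= thr_high <= 1, got {self.thr_low} / {self.thr_high}"
            )
        if self.min_area == 0 and self.max_area == 0:
            lo, hi = derived_area_band(self.se_radius)
            object.__setattr__(self, "min_area", lo)
            object.__setattr__(self, "max_area", hi)
        if not (0 < self.min_area <= self.max_area):
            raise ValueError(
                f"require 0 < min_area <= max_area, got {self.min_area} / {self.max_area}"
            )
        if not (0 <= self.min_circularity <= 1):
            raise ValueError(f"min_circularity must lie in [0, 1], got {self.min_circularity}")
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown detection parameter(s): {sorted(unknown)}")
        return cls(**d)


def _format_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return f'"{v}"'


def write_config(params: DetectionParams, path: str | Path) -> None:
    """Write a flat TOML config mirroring :class:`DetectionParams`."""
    lines = [f"{k} = {_format_value(v)}" for k, v in params.to_dict().items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> DetectionParams:
    """Read a flat TOML config written by :func:`write_config`."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return DetectionParams.from_dict(data)
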