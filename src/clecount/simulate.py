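"""Synthetic endomicroscopy video with known ground truth.

Emulates what the counting pipeline actually sees in airway
endomicroscopy of fluorescently labeled cells: a circular field of view
on a dark frame, bright roughly circular cells rendered as isotropic
Gaussian spots, smaller bright debris specks, a textured
autofluorescence background, and frame-to-frame appearance and
disappearance of cells caused by probe and respiratory motion.  Every
draw is controlled by one integer seed, so videos, ground truth and all
downstream statistics are exactly reproducible.

The generator is deliberately simple where the optics are complicated:
no fiber-bundle honeycomb, no within-field drift, no photobleaching.
Cells enter and leave the field by a Bernoulli-persistence /
Poisson-birth process whose stationary visible count is ``cell_rate``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .core import Frame, circular_mask

#: Gaussian sigma of a rendered cell as a fraction of its nominal
#: radius.  With sigma = radius / 2 the granulometric pattern-spectrum
#: peak of a clean spot lands within one pixel of the nominal radius.
SIGMA_PER_RADIUS = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic video generator.

    Defaults describe the study conditions the package is tested under:
    512 x 512 frames, a circular FOV filling 90% of the short edge,
    two-minute acquisitions stood in for by 240 frames, on average 3.6
    visible cells per frame with peak amplitude 10x the background
    noise standard deviation, and 10 sub-resolution debris specks per
    frame.
    """

    frame_height: int = 512
    frame_width: int = 512
    fov_radius_fraction: float = 0.45
    n_frames: int = 240
    cell_rate: float = 3.6
    cell_radius_mean: float = 5.0
    cell_radius_sd: float = 0.5
    cell_peak_snr: float = 10.0
    debris_rate: float = 10.0
    debris_radius_max: float = 1.0
    background_level: float = 20.0
    background_noise_sd: float = 2.0
    background_texture_scale: float = 1.5
    persistence: float = 0.8
    min_separation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_height < 8 or self.frame_width < 8:
            raise ValueError("frame dimensions must be at least 8 pixels")
        if not (0 < self.fov_radius_fraction <= 0.5):
            raise ValueError("fov_radius_fraction must lie in (0, 0.5]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        for name in ("cell_rate", "debris_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("cell_radius_mean", "debris_radius_max", "background_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cell_radius_sd < 0 or self.background_level < 0:
            raise ValueError("cell_radius_sd and background_level must be nonnegative")
        if self.cell_peak_snr <= 0 or self.background_texture_scale <= 0:
            raise ValueError("cell_peak_snr and background_texture_scale must be positive")
        if not (0 <= self.persistence <= 1):
            raise ValueError("persistence must lie in [0, 1]")
        if self.fov_radius < 2 * self.cell_radius_mean:
            raise ValueError(
                f"FOV radius {self.fov_radius:.1f} px too small for cells of "
                f"radius {self.cell_radius_mean} px"
            )

    @property
    def fov_radius(self) -> float:
        return self.fov_radius_fraction * min(self.frame_height, self.frame_width)

    @property
    def cell_amplitude(self) -> float:
        """Peak intensity of a nominal cell above the local background."""
        return self.cell_peak_snr * self.background_noise_sd


@dataclass(frozen=True)
class TrueObject:
    """A simulated cell or debris speck in one frame."""

    centroid_row: float
    centroid_col: float
    radius: float
    amplitude: float


@dataclass
class FrameTruth:
    """Ground truth of one frame; ``true_count`` counts cells only."""

    frame_index: int
    cells: list[TrueObject] = field(default_factory=list)
    debris: list[TrueObject] = field(default_factory=list)

    @property
    def true_count(self) -> int:
        return len(self.cells)


@dataclass
class GroundTruth:
    """Per-frame ground truth of one simulated video."""

    frames: list[FrameTruth]

    @property
    def true_counts(self) -> np.ndarray:
        return np.array([f.true_count for f in self.frames], dtype=int)


@dataclass
class DetectionScore:
    """Centroid-matching score of detections against one frame's truth."""

    true_positives: int
    false_positives: int
    false_negatives: int

    @property
    def precision(self) -> float:
        n = self.true_positives + self.false_positives
        return self.true_positives / n if n else 1.0

    @property
    def recall(self) -> float:
        n = self.true_positives + self.false_negatives
        return self.true_positives / n if n else 1.0

    def __add__(self, other: "DetectionScore") -> "DetectionScore":
        return DetectionScore(
            self.true_positives + other.true_positives,
            self.false_positives + other.false_positives,
            self.false_negatives + other.false_negatives,
        )


def _fov_center(config: SimulationConfig) -> tuple[float, float]:
    return ((config.frame_height - 1) / 2.0, (config.frame_width - 1) / 2.0)


def _sample_position(
    rng: np.random.Generator,
    config: SimulationConfig,
    margin: float,
    existing: Sequence[TrueObject] = (),
) -> tuple[float, float]:
    """Uniform position in the FOV, ``margin`` pixels clear of the rim.

    With ``min_separation`` set, rejection-samples away from existing
    objects (bounded retries; the last candidate is accepted if the
    field is crowded).
    """
    cr, cc = _fov_center(config)
    rmax = max(config.fov_radius - margin, 1.0)
    for _ in range(200):
        rho = rmax * math.sqrt(rng.random())
        theta = 2 * math.pi * rng.random()
        pos = (cr + rho * math.sin(theta), cc + rho * math.cos(theta))
        if config.min_separation is None or all(
            math.hypot(pos[0] - o.centroid_row, pos[1] - o.centroid_col)
            >= config.min_separation
            for o in existing
        ):
            return pos
    return pos


def _new_cell(rng: np.random.Generator, config: SimulationConfig,
              existing: Sequence[TrueObject]) -> TrueObject:
    radius = float(
        np.clip(
            rng.normal(config.cell_radius_mean, config.cell_radius_sd),
            max(1.5, config.cell_radius_mean - 3 * config.cell_radius_sd),
            config.cell_radius_mean + 3 * config.cell_radius_sd,
        )
    )
    # cells are placed fully inside the FOV: ground truth counts whole
    # visible cells, mirroring what an observer would call a cell
    row, col = _sample_position(rng, config, margin=radius, existing=existing)
    amplitude = config.cell_amplitude * rng.uniform(0.9, 1.1)
    return TrueObject(row, col, radius, amplitude)


def _new_debris(rng: np.random.Generator, config: SimulationConfig) -> TrueObject:
    radius = rng.uniform(0.3, config.debris_radius_max)
    row, col = _sample_position(rng, config, margin=radius)
    amplitude = config.cell_amplitude * rng.uniform(0.8, 1.2)
    return TrueObject(row, col, radius, amplitude)


def _add_spot(image: np.ndarray, obj: TrueObject) -> None:
    """Add an isotropic Gaussian spot in place over a local window."""
    sigma = max(obj.radius * SIGMA_PER_RADIUS, 0.3)
    half = int(math.ceil(3.5 * sigma)) + 1
    r0, c0 = int(round(obj.centroid_row)), int(round(obj.centroid_col))
    h, w = image.shape
    rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, h)
    clo, chi = max(c0 - half, 0), min(c0 + half + 1, w)
    if rlo >= rhi or clo >= chi:
        return
    rr = np.arange(rlo, rhi)[:, None] - obj.centroid_row
    cc = np.arange(clo, chi)[None, :] - obj.centroid_col
    image[rlo:rhi, clo:chi] += obj.amplitude * np.exp(
        -(rr**2 + cc**2) / (2 * sigma**2)
    )


def _background(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    """Constant offset plus white noise smoothed at the texture scale."""
    noise = rng.standard_normal((config.frame_height, config.frame_width))
    texture = ndimage.gaussian_filter(noise, config.background_texture_scale)
    sd = texture.std()
    if sd > 0:
        texture *= config.background_noise_sd / sd
    return config.background_level + texture


def render_frame(truth: FrameTruth, config: SimulationConfig,
                 rng: np.random.Generator) -> Frame:
    """Render one frame from its ground truth (background is drawn fresh)."""
    image = _background(rng, config)
    for obj in truth.cells:
        _add_spot(image, obj)
    for obj in truth.debris:
        _add_spot(image, obj)
    fov = circular_mask(image.shape, config.fov_radius, _fov_center(config))
    image[~fov] = 0.0
    np.clip(image, 0.0, None, out=image)
    return Frame(pixels=image, fov_mask=fov, frame_index=truth.frame_index)


def _streams(config: SimulationConfig) -> tuple[np.random.Generator, ...]:
    """Independent RNG streams for cells, debris and background.

    Separate streams mean that changing ``debris_rate`` (or the
    background) leaves the cell realization untouched, so videos that
    differ only in debris density are directly comparable frame by
    frame.
    """
    ss = np.random.SeedSequence(config.seed)
    return tuple(np.random.default_rng(c) for c in ss.spawn(3))


def _evolve_truth(
    config: SimulationConfig,
    rng_cells: np.random.Generator,
    rng_debris: np.random.Generator,
) -> list[FrameTruth]:
    """Bernoulli-persistence / Poisson-birth cell dynamics plus fresh debris.

    With persistence p, the birth rate lambda*(1-p) keeps the stationary
    expected visible count at ``cell_rate``; frame 0 starts at
    stationarity.  Debris is redrawn every frame (it washes through the
    field much faster than cells do).
    """
    birth_rate = config.cell_rate * (1.0 - config.persistence)
    frames: list[FrameTruth] = []
    cells: list[TrueObject] = []
    for i in range(config.n_frames):
        if i == 0:
            n0 = rng_cells.poisson(config.cell_rate)
            for _ in range(n0):
                cells.append(_new_cell(rng_cells, config, cells))
        else:
            survivors = [c for c in cells if rng_cells.random() < config.persistence]
            cells = survivors
            for _ in range(rng_cells.poisson(birth_rate)):
                cells.append(_new_cell(rng_cells, config, cells))
        debris = [
            _new_debris(rng_debris, config)
            for _ in range(rng_debris.poisson(config.debris_rate))
        ]
        frames.append(FrameTruth(frame_index=i, cells=list(cells), debris=debris))
    return frames


def generate_video(config: SimulationConfig) -> tuple[np.ndarray, GroundTruth]:
    """Simulate one video: (n_frames, H, W) float array plus ground truth.

    Fully reproducible from ``config.seed``.
    """
    rng_cells, rng_debris, rng_bg = _streams(config)
    truth_frames = _evolve_truth(config, rng_cells, rng_debris)
    video = np.empty(
        (config.n_frames, config.frame_height, config.frame_width), dtype=np.float64
    )
    for i, ft in enumerate(truth_frames):
        video[i] = render_frame(ft, config, rng_bg).pixels
    return video, GroundTruth(frames=truth_frames)


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Ground truth only, without rendering pixels (cheap for long runs)."""
    rng_cells, rng_debris, _ = _streams(config)
    return GroundTruth(frames=_evolve_truth(config, rng_cells, rng_debris))


def iter_video_frames(config: SimulationConfig) -> Iterator[tuple[Frame, FrameTruth]]:
    """Stream (frame, truth) pairs without holding the whole video in memory."""
    rng_cells, rng_debris, rng_bg = _streams(config)
    for ft in _evolve_truth(config, rng_cells, rng_debris):
        yield render_frame(ft, config, rng_bg), ft


@dataclass(frozen=True)
class GroupSpec:
    """One arm of a simulated study."""

    condition: str  # e.g. "Ctrl" or "RT"
    route: str  # e.g. "ET" or "IV"
    cell_rate: float
    n_rats: int
    videos_per_rat: int = 2


@dataclass
class SimulatedVideo:
    """One labeled study video with its ground truth and generator config."""

    video_id: str
    rat_id: str
    route: str
    condition: str
    config: SimulationConfig
    truth: GroundTruth

    def frames(self) -> Iterator[tuple[Frame, FrameTruth]]:
        return iter_video_frames(self.config)


def generate_study(
    groups: Sequence[GroupSpec],
    base_config: SimulationConfig,
    seed: int,
) -> list[SimulatedVideo]:
    """Lay out a multi-arm study with deterministic per-video sub-seeds.

    Each rat belongs to exactly one (condition, route) arm; every video
    gets its own child seed spawned from the master seed, so any video
    can be re-rendered in isolation.  Pixel data are not materialized
    here; iterate ``SimulatedVideo.frames()`` to render.
    """
    if not groups:
        raise ValueError("need at least one group spec")
    ss = np.random.SeedSequence(seed)
    n_videos = sum(g.n_rats * g.videos_per_rat for g in groups)
    children = ss.spawn(n_videos)
    out: list[SimulatedVideo] = []
    k = 0
    for g in groups:
        for rat in range(g.n_rats):
            rat_id = f"{g.condition}-{g.route}-r{rat + 1:02d}"
            for vid in range(g.videos_per_rat):
                sub_seed = int(children[k].generate_state(1, dtype=np.uint32)[0] % (2**31))
                k += 1
                cfg = replace(base_config, cell_rate=g.cell_rate, seed=sub_seed)
                rc, rd, _ = _streams(cfg)
                truth = GroundTruth(frames=_evolve_truth(cfg, rc, rd))
                out.append(
                    SimulatedVideo(
                        video_id=f"{rat_id}-v{vid + 1}",
                        rat_id=rat_id,
                        route=g.route,
                        condition=g.condition,
                        config=cfg,
                        truth=truth,
                    )
                )
    return out


def score_detections(
    detected: Sequence[tuple[float, float]] | "np.ndarray",
    truth: FrameTruth,
    match_radius: float,
) -> DetectionScore:
    """Greedy one-to-one nearest-neighbor matching of detections to true cells.

    Pairs are matched in order of increasing centroid distance; pairs
    farther apart than ``match_radius`` stay unmatched.  Unmatched
    detections are false positives, unmatched true cells false
    negatives.  Debris is never a legitimate target: a detection landing
    on debris counts as a false positive.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    det = np.asarray(
        [(d.centroid_row, d.centroid_col) if hasattr(d, "centroid_row") else d for d in detected],
        dtype=float,
    ).reshape(-1, 2)
    tru = np.asarray(
        [(c.centroid_row, c.centroid_col) for c in truth.cells], dtype=float
    ).reshape(-1, 2)
    n_det, n_tru = len(det), len(tru)
    if n_det == 0 or n_tru == 0:
        return DetectionScore(0, n_det, n_tru)
    dist = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
    pairs = [
        (dist[i, j], i, j)
        for i in range(n_det)
        for j in range(n_tru)
        if dist[i, j] <= match_radius
    ]
    pairs.sort()
    used_det: set[int] = set()
    used_tru: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        tp += 1
    return DetectionScore(tp, n_det - tp, n_tru - tp)
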