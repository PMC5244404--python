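"""Reading video stacks and writing counts, masks and ground truth.

Input videos are multi-page TIFF stacks or directories of
lexicographically ordered single-frame TIFF/PNG images.  RGB input is
reduced to the red channel by default — labeled cells are imaged in the
red channel — with an optional luminance reduction.  All outputs are
written atomically (temporary file + rename) so an interrupted run
leaves no partial artifact behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import Frame
from .detection import FrameDetection
from .simulate import GroundTruth

#: ITU-R BT.601 luma weights, used for the optional luminance reduction.
_LUMA = np.array([0.299, 0.587, 0.114])

FRAME_SUFFIXES = (".tif", ".tiff", ".png")


def _reduce_channels(arr: np.ndarray, channel: str) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3].astype(np.float64)
        if channel == "red":
            return rgb[..., 0]
        if channel == "luminance":
            return rgb @ _LUMA
        raise ValueError(f"unknown channel reduction {channel!r}")
    raise ValueError(f"cannot interpret image of shape {arr.shape} as a grayscale frame")


def iter_frames(path: str | Path, channel: str = "red") -> Iterator[Frame]:
    """Yield frames from a TIFF stack or a directory of numbered images.

    ``channel`` controls RGB reduction: ``red`` (default) or
    ``luminance``.  Frames get consecutive ``frame_index`` values in
    page or filename order.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in FRAME_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG frames found in {path}")
        for i, f in enumerate(files):
            arr = iio.imread(f)
            yield Frame(_reduce_channels(np.asarray(arr), channel), frame_index=i)
    else:
        if not path.exists():
            raise FileNotFoundError(str(path))
        with tifffile.TiffFile(path) as tf:
            for i, page in enumerate(tf.pages):
                arr = page.asarray()
                yield Frame(_reduce_channels(np.asarray(arr), channel), frame_index=i)


def read_video(path: str | Path, channel: str = "red") -> list[Frame]:
    """Load every frame of a video into memory (see :func:`iter_frames`)."""
    return list(iter_frames(path, channel))


def atomic_write(path: str | Path, write_fn) -> None:
    """Write a file via a temporary sibling and an atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def detections_to_table(detections: Sequence[FrameDetection]) -> pd.DataFrame:
    """Tidy per-object table; frames with no objects keep one row of NaNs.

    Columns: frame_index, count, centroid_row, centroid_col, area,
    perimeter, circularity, mean_intensity.
    """
    rows = []
    for det in detections:
        if not det.objects:
            rows.append(
                dict(frame_index=det.frame_index, count=0, centroid_row=np.nan,
                     centroid_col=np.nan, area=np.nan, perimeter=np.nan,
                     circularity=np.nan, mean_intensity=np.nan)
            )
        for obj in det.objects:
            rows.append(
                dict(frame_index=det.frame_index, count=det.count,
                     centroid_row=obj.centroid_row, centroid_col=obj.centroid_col,
                     area=obj.area, perimeter=obj.perimeter,
                     circularity=obj.circularity, mean_intensity=obj.mean_intensity)
            )
    return pd.DataFrame(rows)


def write_counts_csv(detections: Sequence[FrameDetection], path: str | Path) -> None:
    table = detections_to_table(detections)
    atomic_write(path, lambda tmp: table.to_csv(tmp, index=False))


def read_counts_csv(path: str | Path) -> pd.Series:
    """Per-frame counts (indexed by frame_index) from a counts CSV."""
    df = pd.read_csv(path)
    counts = df.groupby("frame_index")["count"].first().sort_index()
    return counts.astype(int)


def write_masks_tiff(masks: Sequence[np.ndarray], path: str | Path) -> None:
    """Write binary masks as an 8-bit multi-page TIFF (255 = foreground)."""
    stack = np.stack([m.astype(np.uint8) * 255 for m in masks])
    atomic_write(
        path, lambda tmp: tifffile.imwrite(tmp, stack, photometric="minisblack")
    )


def write_video_tiff(video: np.ndarray, path: str | Path) -> None:
    """Write a float video stack as 32-bit multi-page TIFF."""
    atomic_write(
        path,
        lambda tmp: tifffile.imwrite(
            tmp, video.astype(np.float32), photometric="minisblack"
        ),
    )


def truth_to_table(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth objects as a tidy table (one row per object)."""
    rows = []
    for ft in truth.frames:
        for kind, objs in (("cell", ft.cells), ("debris", ft.debris)):
            for o in objs:
                rows.append(
                    dict(frame_index=ft.frame_index, object_type=kind,
                         centroid_row=o.centroid_row, centroid_col=o.centroid_col,
                         radius=o.radius, amplitude=o.amplitude)
                )
        if not ft.cells and not ft.debris:
            rows.append(
                dict(frame_index=ft.frame_index, object_type="none",
                     centroid_row=np.nan, centroid_col=np.nan,
                     radius=np.nan, amplitude=np.nan)
            )
    return pd.DataFrame(rows)


def write_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    atomic_write(path, lambda tmp: truth_to_table(truth).to_csv(tmp, index=False))
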