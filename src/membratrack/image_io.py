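"""Calibrated time-lapse I/O: TIFF stacks in, label masks and track tables out.

Coordinate convention used throughout the package: 0-based raster
coordinates with ``x`` the column index (increasing rightward) and ``y``
the row index (increasing downward); pixel centers sit at integer
coordinates.  The motility module converts to mathematical orientation
(y up) explicitly when directions are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "FrameStack",
    "LabelMask",
    "read_stack",
    "max_project_z",
    "write_label_masks",
    "read_label_masks",
    "write_tracks_csv",
]

TRACK_CSV_COLUMNS = ["track_id", "frame", "x_px", "y_px", "area_px2", "x_um", "y_um"]


@dataclass
class FrameStack:
    """Time-ordered 2-D intensity frames with physical calibration.

    Parameters
    ----------
    frames
        List of 2-D float arrays (rows = y, columns = x), one per timepoint.
    pixel_size_um
        Physical pixel size in micrometres (> 0).
    frame_interval_min
        Minutes between consecutive frames (> 0).
    z_planes
        Optional list of 3-D arrays ``(z, y, x)``, one per timepoint, when
        the source was volumetric.  ``frames`` then normally holds a
        projection of these planes.
    """

    frames: list[np.ndarray]
    pixel_size_um: float
    frame_interval_min: float
    z_planes: list[np.ndarray] | None = None
    source_dtype: np.dtype | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.frame_interval_min <= 0:
            raise ValueError(
                f"frame_interval_min must be > 0, got {self.frame_interval_min}"
            )
        if len(self.frames) < 1:
            raise ValueError("a FrameStack needs at least one frame")
        shape = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.ndim != 2:
                raise ValueError(f"frame {i} is not 2-D (shape {f.shape})")
            if f.shape != shape:
                raise ValueError(
                    f"frame {i} shape {f.shape} differs from frame 0 shape {shape}"
                )
            if not np.all(np.isfinite(f)):
                raise ValueError(f"frame {i} contains non-finite intensities")
            if np.any(f < 0):
                raise ValueError(f"frame {i} contains negative intensities")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape


@dataclass
class LabelMask:
    """Per-frame integer segmentation.

    ``labels`` holds 0 for background/excluded pixels and values ``1..K``
    (consecutive, no gaps) for cell regions.
    """

    labels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        m = int(self.labels.max(initial=0))
        return m

    def label_values(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]


def read_stack(
    path: str | Path,
    pixel_size_um: float,
    frame_interval_min: float,
    *,
    axes: str | None = None,
) -> FrameStack:
    """Read a single- or multi-page TIFF into a :class:`FrameStack`.

    Each page becomes one frame; for a TZYX hyperstack every timepoint's
    z-planes are kept in ``z_planes`` and ``frames`` holds the first plane
    (call :func:`max_project_z` to project).  Intensities are converted to
    float64 but preserved bit-exactly relative to the stored values.

    Parameters
    ----------
    axes
        Explicit dimension order (``"TYX"`` or ``"TZYX"``); by default the
        order is inferred from the array rank.
    """
    path = Path(path)
    if pixel_size_um <= 0 or frame_interval_min <= 0:
        raise ValueError("calibration values must be positive")
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise ValueError(f"{path} contains no image pages")
    shape0 = pages[0].shape
    for i, p in enumerate(pages):
        if p.shape != shape0:
            raise ValueError(
                f"page {i} shape {p.shape} differs from page 0 shape {shape0}"
            )
    arr = np.stack(pages)
    src_dtype = arr.dtype

    if axes is None:
        axes = "TZYX" if arr.ndim == 4 else "TYX"
    axes = axes.upper()
    if axes == "TYX":
        if arr.ndim == 4:
            raise ValueError("4-D data requires axes='TZYX'")
        frames = [f.astype(np.float64) for f in arr]
        z_planes = None
    elif axes == "TZYX":
        if arr.ndim == 3:
            # pages are z-planes of a single timepoint
            arr = arr[np.newaxis]
        z_planes = [v.astype(np.float64) for v in arr]
        frames = [v[0] for v in z_planes]
    else:
        raise ValueError(f"unsupported axes order {axes!r}; use TYX or TZYX")
    return FrameStack(
        frames=frames,
        pixel_size_um=float(pixel_size_um),
        frame_interval_min=float(frame_interval_min),
        z_planes=z_planes,
        source_dtype=src_dtype,
    )


def write_stack(stack: FrameStack, path: str | Path, dtype=None) -> None:
    """Write the stack's frames as a multi-page TIFF (one page per frame)."""
    data = np.stack(stack.frames)
    if dtype is not None:
        data = data.astype(dtype)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def max_project_z(stack: FrameStack) -> FrameStack:
    """Maximum-intensity projection over z for every timepoint.

    Calibration is copied; the result has no z-planes (projection is
    idempotent).
    """
    if stack.z_planes is None:
        raise ValueError("stack has no z-planes to project")
    projected = [vol.max(axis=0, keepdims=True) for vol in stack.z_planes]
    return FrameStack(
        frames=[v[0] for v in projected],
        pixel_size_um=stack.pixel_size_um,
        frame_interval_min=stack.frame_interval_min,
        z_planes=projected,  # depth-1 volumes: projecting again is the identity
        source_dtype=stack.source_dtype,
    )


def write_label_masks(masks: Sequence[LabelMask], path: str | Path) -> None:
    """Write label masks as a 16-bit multi-page TIFF, one page per frame."""
    if len(masks) == 0:
        raise ValueError("mask list is empty")
    shape = masks[0].labels.shape
    pages = []
    for m in masks:
        if m.labels.shape != shape:
            raise ValueError("all masks must share the same shape")
        if m.labels.max(initial=0) > 65535:
            raise ValueError(
                f"frame {m.frame_index}: label {int(m.labels.max())} exceeds "
                "the 16-bit capacity (65535)"
            )
        pages.append(m.labels.astype(np.uint16))
    tifffile.imwrite(Path(path), np.stack(pages), photometric="minisblack")


def read_label_masks(path: str | Path) -> list[LabelMask]:
    """Read back masks written by :func:`write_label_masks`."""
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return [LabelMask(labels=page.astype(np.int64), frame_index=i) for i, page in enumerate(arr)]


def write_tracks_csv(trackset, path: str | Path, pixel_size_um: float) -> None:
    """Write a TrackSet as a CSV sorted by (track_id, frame).

    Columns: ``track_id,frame,x_px,y_px,area_px2,x_um,y_um``; micrometre
    columns are the pixel centroids scaled by ``pixel_size_um``.
    """
    rows = []
    for track in trackset.tracks:
        for frame_index, det in track.points:
            x, y = det.centroid_xy_px
            rows.append(
                {
                    "track_id": track.id,
                    "frame": frame_index,
                    "x_px": x,
                    "y_px": y,
                    "area_px2": det.area_px2,
                    "x_um": x * pixel_size_um,
                    "y_um": y * pixel_size_um,
                }
            )
    df = pd.DataFrame(rows, columns=TRACK_CSV_COLUMNS)
    if len(df):
        df = df.sort_values(["track_id", "frame"], kind="stable")
    df.to_csv(Path(path), index=False, float_format="%.6f")


def read_tracks_csv(path: str | Path):
    """Rebuild a TrackSet from a tracks CSV written by this package."""
    from .segmentation import Detection
    from .tracking import Track, TrackSet

    df = pd.read_csv(Path(path))
    ts = TrackSet()
    for tid, group in df.groupby("track_id", sort=True):
        points = []
        for row in group.sort_values("frame").itertuples():
            det = Detection(
                frame_index=int(row.frame),
                label=0,
                centroid_xy_px=(float(row.x_px), float(row.y_px)),
                area_px2=int(row.area_px2),
            )
            points.append((int(row.frame), det))
        ts.tracks.append(Track(id=int(tid), points=points))
    ts._next_id = max((t.id for t in ts.tracks), default=-1) + 1
    return ts
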