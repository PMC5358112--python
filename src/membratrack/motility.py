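"""Motility read-outs: movement vectors, wind rose, region time series.

Directions use mathematical orientation: x increases rightward as in the
raster, but y is flipped so that "up" in the displayed image is 90 deg.
The wind rose follows polar-histogram semantics: spoke length is the
proportion of counted movement vectors whose direction falls in that
sector, and the colour bands within a spoke subdivide the proportion by
speed, so per-sector band fractions sum to the sector proportion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .image_io import FrameStack, LabelMask
from .segmentation import extract_detections
from .tracking import TrackSet

__all__ = [
    "MotilityStep",
    "WindRose",
    "RegionTimeSeries",
    "compute_steps",
    "net_displacements",
    "windrose",
    "region_time_series",
    "plot_windrose",
]

DEFAULT_N_SECTORS = 16
DEFAULT_BAND_EDGES = (0.0, 0.05, 0.1, 0.2)


@dataclass
class MotilityStep:
    """Displacement of one tracked cell between two observed frames.

    ``t1 - t0`` is 1 for consecutive observations and larger when the
    track bridged missed frames; elapsed time scales accordingly.
    Zero-displacement steps carry direction 0 deg by convention and are
    flagged degenerate so the wind rose can exclude them.
    """

    track_id: int
    t0: int
    t1: int
    displacement_um: tuple[float, float]
    speed_um_per_min: float
    direction_deg: float
    degenerate: bool = False


@dataclass
class WindRose:
    sector_edges_deg: np.ndarray  # n_sectors+1 ascending bounds spanning 360
    proportions: np.ndarray  # per-sector fraction of counted vectors
    band_edges_um_per_min: np.ndarray  # lower bounds of speed bands
    band_fractions: np.ndarray  # (n_sectors, n_bands)
    n_vectors: int
    mode: str
    empty: bool = False

    def to_dict(self) -> dict:
        return {
            "sector_edges_deg": self.sector_edges_deg.tolist(),
            "proportions": self.proportions.tolist(),
            "band_edges": self.band_edges_um_per_min.tolist(),
            "band_fractions": self.band_fractions.tolist(),
            "n_vectors": self.n_vectors,
            "mode": self.mode,
            "empty": self.empty,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @property
    def modal_sector_center_deg(self) -> float:
        i = int(np.argmax(self.proportions))
        lo, hi = self.sector_edges_deg[i], self.sector_edges_deg[i + 1]
        return float(((lo + hi) / 2.0) % 360.0)


@dataclass
class RegionTimeSeries:
    """Per-frame, per-region cell counts and mean areas (um^2)."""

    table: pd.DataFrame  # columns: frame, region, count, mean_area_um2

    def counts(self, region: str) -> np.ndarray:
        sub = self.table[self.table.region == region].sort_values("frame")
        return sub["count"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(Path(path), index=False, float_format="%.6f")


def _vector_to_polar(dx_um: float, dy_um_math: float, minutes: float):
    norm = float(np.hypot(dx_um, dy_um_math))
    speed = norm / minutes
    if norm == 0.0:
        return speed, 0.0, True
    direction = float(np.degrees(np.arctan2(dy_um_math, dx_um)) % 360.0)
    return speed, direction, False


def compute_steps(
    trackset: TrackSet, pixel_size_um: float, frame_interval_min: float
) -> list[MotilityStep]:
    """One MotilityStep per consecutive observed point pair in each track."""
    if pixel_size_um <= 0 or frame_interval_min <= 0:
        raise ValueError("calibration values must be positive")
    steps: list[MotilityStep] = []
    for track in trackset.tracks:
        for (t0, d0), (t1, d1) in zip(track.points, track.points[1:]):
            dx = (d1.centroid_xy_px[0] - d0.centroid_xy_px[0]) * pixel_size_um
            dy_raster = (d1.centroid_xy_px[1] - d0.centroid_xy_px[1]) * pixel_size_um
            dy = -dy_raster  # mathematical orientation: y up
            minutes = (t1 - t0) * frame_interval_min
            speed, direction, degenerate = _vector_to_polar(dx, dy, minutes)
            steps.append(
                MotilityStep(
                    track_id=track.id,
                    t0=t0,
                    t1=t1,
                    displacement_um=(dx, dy),
                    speed_um_per_min=speed,
                    direction_deg=direction,
                    degenerate=degenerate,
                )
            )
    return steps


def net_displacements(
    trackset: TrackSet, pixel_size_um: float, frame_interval_min: float
) -> list[MotilityStep]:
    """Aggregate each track to a single first-to-last displacement vector.

    This is the default wind-rose input — one vote per cell over the
    analysis window.  Tracks with fewer than two observations are
    skipped.
    """
    if pixel_size_um <= 0 or frame_interval_min <= 0:
        raise ValueError("calibration values must be positive")
    vectors: list[MotilityStep] = []
    for track in trackset.tracks:
        if len(track.points) < 2:
            continue
        t0, d0 = track.points[0]
        t1, d1 = track.points[-1]
        dx = (d1.centroid_xy_px[0] - d0.centroid_xy_px[0]) * pixel_size_um
        dy = -(d1.centroid_xy_px[1] - d0.centroid_xy_px[1]) * pixel_size_um
        minutes = (t1 - t0) * frame_interval_min
        speed, direction, degenerate = _vector_to_polar(dx, dy, minutes)
        vectors.append(
            MotilityStep(
                track_id=track.id,
                t0=t0,
                t1=t1,
                displacement_um=(dx, dy),
                speed_um_per_min=speed,
                direction_deg=direction,
                degenerate=degenerate,
            )
        )
    return vectors


def windrose(
    vectors: Sequence[MotilityStep],
    n_sectors: int = DEFAULT_N_SECTORS,
    band_edges: Sequence[float] = DEFAULT_BAND_EDGES,
    min_speed: float = 0.0,
    mode: str = "net",
) -> WindRose:
    """Bin movement vectors into a direction x speed wind rose.

    Sectors are half-open ``[edge_i, edge_{i+1})`` with the first sector
    centred on 0 deg; speed bands are half-open with the last band
    unbounded above.  Vectors slower than ``min_speed`` and degenerate
    (zero-displacement) vectors are excluded; proportions are computed
    over the vectors kept.
    """
    if n_sectors < 2:
        raise ValueError("n_sectors must be >= 2")
    band_edges = np.asarray(band_edges, dtype=np.float64)
    if band_edges.ndim != 1 or len(band_edges) < 1:
        raise ValueError("band_edges must be a non-empty 1-D sequence")
    if np.any(np.diff(band_edges) <= 0):
        raise ValueError("band_edges must be strictly ascending")
    if min_speed < 0:
        raise ValueError("min_speed must be >= 0")

    width = 360.0 / n_sectors
    half = width / 2.0
    sector_edges = -half + width * np.arange(n_sectors + 1)
    n_bands = len(band_edges)

    kept = [
        v
        for v in vectors
        if not v.degenerate and v.speed_um_per_min >= min_speed
    ]
    counts = np.zeros((n_sectors, n_bands), dtype=np.int64)
    for v in kept:
        si = int(((v.direction_deg + half) % 360.0) // width)
        si = min(si, n_sectors - 1)  # guard against float wrap at 360-half
        bi = int(np.searchsorted(band_edges, v.speed_um_per_min, side="right")) - 1
        bi = max(bi, 0)
        counts[si, bi] += 1

    total = counts.sum()
    if total == 0:
        return WindRose(
            sector_edges_deg=sector_edges,
            proportions=np.zeros(n_sectors),
            band_edges_um_per_min=band_edges,
            band_fractions=np.zeros((n_sectors, n_bands)),
            n_vectors=0,
            mode=mode,
            empty=True,
        )
    band_fractions = counts / total
    return WindRose(
        sector_edges_deg=sector_edges,
        proportions=band_fractions.sum(axis=1),
        band_edges_um_per_min=band_edges,
        band_fractions=band_fractions,
        n_vectors=int(total),
        mode=mode,
        empty=False,
    )


def region_time_series(
    masks: Sequence[LabelMask],
    frames: FrameStack,
    split_x_px: float | None = None,
) -> RegionTimeSeries:
    """Left/right cell counts and mean areas per frame.

    Cells are assigned by centroid: ``x < split_x_px`` left, otherwise
    right (cells exactly on the split count right).  Areas are converted
    to um^2 with the stack's pixel size.  An ``all`` region aggregates
    the whole field.
    """
    if len(masks) != frames.n_frames:
        raise ValueError("number of masks and frames differ")
    h, w = frames.shape
    if split_x_px is None:
        split_x_px = w / 2.0
    if not 0 <= split_x_px <= w:
        raise ValueError(f"split_x_px {split_x_px} outside field width {w}")
    px_area = frames.pixel_size_um**2
    rows = []
    for t, (mask, frame) in enumerate(zip(masks, frames.frames)):
        dets = extract_detections(mask, frame, frame_index=t)
        groups = {"left": [], "right": [], "all": []}
        for d in dets:
            side = "left" if d.centroid_xy_px[0] < split_x_px else "right"
            groups[side].append(d)
            groups["all"].append(d)
        for region, ds in groups.items():
            rows.append(
                {
                    "frame": t,
                    "region": region,
                    "count": len(ds),
                    "mean_area_um2": (
                        float(np.mean([d.area_px2 for d in ds]) * px_area)
                        if ds
                        else np.nan
                    ),
                }
            )
    return RegionTimeSeries(table=pd.DataFrame(rows))


def plot_windrose(rose: WindRose, path: str | Path) -> None:
    """Render the wind rose as an SVG polar plot (stacked speed bands)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_sectors = len(rose.proportions)
    centers_deg = (rose.sector_edges_deg[:-1] + rose.sector_edges_deg[1:]) / 2.0
    theta = np.radians(centers_deg)
    width = np.radians(360.0 / n_sectors)
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(111, projection="polar")
    bottom = np.zeros(n_sectors)
    cmap = plt.get_cmap("viridis")
    n_bands = rose.band_fractions.shape[1]
    for b in range(n_bands):
        frac = rose.band_fractions[:, b]
        lo = rose.band_edges_um_per_min[b]
        label = (
            f">= {lo:g} um/min"
            if b == n_bands - 1
            else f"{lo:g}-{rose.band_edges_um_per_min[b + 1]:g} um/min"
        )
        ax.bar(
            theta,
            frac,
            width=width * 0.95,
            bottom=bottom,
            color=cmap(b / max(n_bands - 1, 1)),
            edgecolor="white",
            linewidth=0.3,
            label=label,
        )
        bottom += frac
    ax.set_theta_zero_location("E")
    ax.set_theta_direction(1)
    ax.legend(loc="lower left", bbox_to_anchor=(1.0, 0.0), fontsize=7)
    ax.set_title(f"cell migration ({rose.n_vectors} vectors, {rose.mode} mode)")
    fig.savefig(Path(path), format="svg", bbox_inches="tight")
    plt.close(fig)
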