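"""Pipeline configuration: defaults, YAML round-trip, validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ridge import DEFAULT_CLOSE_RADIUS, DEFAULT_SIGMAS
from .segmentation import SegmentationParams
from .tracking import DEFAULT_GATE_PX, DEFAULT_MAX_MISSES
from .motility import DEFAULT_BAND_EDGES, DEFAULT_N_SECTORS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run.

    The analysis path is fully deterministic; ``seed`` only feeds
    stochastic options (synthetic generation).  Precedence when built by
    the CLI: command-line flags > config file > these defaults.
    """

    input: str = ""
    output_dir: str = "membratrack_out"
    pixel_size_um: float = 1.0
    frame_interval_min: float = 5.0
    axes: str | None = None  # TYX / TZYX; None = infer from rank
    project_z: bool = True

    ridge_sigmas: tuple[float, ...] = DEFAULT_SIGMAS
    ridge_close_radius: int = DEFAULT_CLOSE_RADIUS

    seg_h_rel: float = 0.10
    seg_min_area_px2: int = 30
    seg_drop_border: bool = False

    track_gate_px: float = DEFAULT_GATE_PX
    track_max_misses: int = DEFAULT_MAX_MISSES

    rose_n_sectors: int = DEFAULT_N_SECTORS
    rose_band_edges: tuple[float, ...] = DEFAULT_BAND_EDGES
    rose_min_speed: float = 0.0
    rose_mode: str = "net"  # one vote per cell; "step" = one per frame pair
    split_x_px: float | None = None  # None = field midline

    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("calibration values must be positive")
        if self.track_gate_px <= 0:
            raise ValueError("track_gate_px must be > 0")
        if self.track_max_misses < 0:
            raise ValueError("track_max_misses must be >= 0")
        if self.rose_mode not in ("net", "step"):
            raise ValueError(f"unknown rose_mode {self.rose_mode!r}")
        if self.rose_n_sectors < 2:
            raise ValueError("rose_n_sectors must be >= 2")
        # delegate segmentation checks
        self.segmentation_params()

    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            sigmas=tuple(self.ridge_sigmas),
            close_radius=self.ridge_close_radius,
            h_rel=self.seg_h_rel,
            min_area_px2=self.seg_min_area_px2,
            drop_border=self.seg_drop_border,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ridge_sigmas"] = list(self.ridge_sigmas)
        d["rose_band_edges"] = list(self.rose_band_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "ridge_sigmas" in d:
            d["ridge_sigmas"] = tuple(float(s) for s in d["ridge_sigmas"])
        if "rose_band_edges" in d:
            d["rose_band_edges"] = tuple(float(b) for b in d["rose_band_edges"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
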