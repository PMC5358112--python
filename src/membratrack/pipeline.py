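"""End-to-end orchestration: read -> (project) -> segment -> track -> motility.

Every run writes its outputs plus a manifest recording the configuration
hash, software version and per-stage counts; reruns with an identical
configuration reproduce identical outputs byte for byte (no timestamps
are embedded).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .image_io import (
    FrameStack,
    write_label_masks,
    write_tracks_csv,
)
from .motility import (
    compute_steps,
    net_displacements,
    plot_windrose,
    region_time_series,
    windrose,
)
from .segmentation import extract_detections, segment_frame
from .tracking import track_sequence

__all__ = ["run_pipeline", "analyse_stack"]

log = logging.getLogger("membratrack")


def analyse_stack(stack: FrameStack, config: PipelineConfig) -> dict:
    """Run segmentation, tracking and motility on an in-memory stack.

    Returns a dict with masks, detections, tracks, steps/net vectors,
    wind rose and region series — the library-level counterpart of
    :func:`run_pipeline` for callers that already hold a FrameStack.
    """
    config.validate()
    seg_params = config.segmentation_params()

    masks = []
    per_frame_dets = []
    for t, frame in enumerate(stack.frames):
        mask = segment_frame(frame, seg_params, frame_index=t)
        masks.append(mask)
        per_frame_dets.append(extract_detections(mask, frame, frame_index=t))
        log.debug("frame %d: %d cells", t, mask.n_labels)

    tracks = track_sequence(
        per_frame_dets,
        gate_px=config.track_gate_px,
        max_misses=config.track_max_misses,
    )

    steps = compute_steps(tracks, stack.pixel_size_um, stack.frame_interval_min)
    if config.rose_mode == "net":
        vectors = net_displacements(
            tracks, stack.pixel_size_um, stack.frame_interval_min
        )
    else:
        vectors = steps
    rose = windrose(
        vectors,
        n_sectors=config.rose_n_sectors,
        band_edges=config.rose_band_edges,
        min_speed=config.rose_min_speed,
        mode=config.rose_mode,
    )
    regions = region_time_series(masks, stack, split_x_px=config.split_x_px)

    return {
        "masks": masks,
        "detections": per_frame_dets,
        "tracks": tracks,
        "steps": steps,
        "vectors": vectors,
        "windrose": rose,
        "regions": regions,
    }


def run_pipeline(
    config: PipelineConfig, stack: FrameStack | None = None
) -> dict:
    """Full run with outputs on disk; returns the run manifest.

    Writes per-frame label masks (16-bit TIFF), the tracks CSV, the
    wind-rose JSON and SVG, the region-series CSV and ``manifest.json``
    into ``config.output_dir``.  On a stage failure the manifest records
    the failed stage and the error, and the exception propagates.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "version": __version__,
        "status": "running",
        "stages": {},
    }
    stage = "read"
    try:
        if stack is None:
            from .image_io import max_project_z, read_stack

            stack = read_stack(
                config.input,
                pixel_size_um=config.pixel_size_um,
                frame_interval_min=config.frame_interval_min,
                axes=config.axes,
            )
            if stack.z_planes is not None and config.project_z:
                stage = "project"
                stack = max_project_z(stack)
        manifest["stages"]["read"] = {
            "n_frames": stack.n_frames,
            "shape": list(stack.shape),
        }

        stage = "analyse"
        result = analyse_stack(stack, config)
        masks = result["masks"]
        dets = result["detections"]
        tracks = result["tracks"]
        manifest["stages"]["segment"] = {
            "detections_per_frame": [len(d) for d in dets],
            "total_detections": sum(len(d) for d in dets),
        }
        manifest["stages"]["track"] = {
            "n_tracks": len(tracks),
            "n_steps": len(result["steps"]),
        }
        manifest["stages"]["motility"] = {
            "n_rose_vectors": result["windrose"].n_vectors,
            "rose_empty": result["windrose"].empty,
        }

        stage = "write"
        write_label_masks(masks, out / "masks.tif")
        write_tracks_csv(tracks, out / "tracks.csv", stack.pixel_size_um)
        result["windrose"].to_json(out / "windrose.json")
        plot_windrose(result["windrose"], out / "windrose.svg")
        result["regions"].to_csv(out / "regions.csv")
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    result["manifest"] = manifest
    return result
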