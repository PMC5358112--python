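"""Frame-to-frame cell tracking by gated optimal assignment.

Tracks are initialized from the detections of the first frame and
extended frame-by-frame: the cost of pairing a live track with a new
detection is the Euclidean centroid distance in pixels, pairs farther
than a distance gate are forbidden, and the minimum-total-cost
one-to-one assignment is found exactly with the Hungarian method (the
Jonker–Volgenant variant of :func:`scipy.optimize.linear_sum_assignment`).
Unmatched tracks accumulate misses — lost, then terminated once
``misses > max_misses`` — and unmatched detections found new tracks.
There is no mitosis model: a dividing cell keeps one child on the old
track and the other founds a new one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .segmentation import Detection

__all__ = [
    "TrackStatus",
    "Track",
    "TrackSet",
    "AssignmentResult",
    "solve_assignment",
    "step_tracks",
    "track_sequence",
    "DEFAULT_GATE_PX",
    "DEFAULT_MAX_MISSES",
]

DEFAULT_GATE_PX = 15.0
DEFAULT_MAX_MISSES = 2
#: cost placed on gated-out (forbidden) pairings; far above any padded cost
FORBIDDEN_COST = 1e9


class TrackStatus(str, Enum):
    ACTIVE = "active"
    LOST = "lost"
    TERMINATED = "terminated"


@dataclass
class Track:
    id: int
    points: list[tuple[int, Detection]] = field(default_factory=list)
    status: TrackStatus = TrackStatus.ACTIVE
    misses: int = 0

    @property
    def last_frame(self) -> int:
        return self.points[-1][0]

    @property
    def last_centroid(self) -> tuple[float, float]:
        return self.points[-1][1].centroid_xy_px

    def append(self, frame_index: int, det: Detection) -> None:
        if self.status is TrackStatus.TERMINATED:
            raise ValueError(f"track {self.id} is terminated")
        if self.points and frame_index <= self.last_frame:
            raise ValueError(
                f"track {self.id}: frame {frame_index} not after {self.last_frame}"
            )
        self.points.append((frame_index, det))
        self.status = TrackStatus.ACTIVE
        self.misses = 0


@dataclass
class TrackSet:
    tracks: list[Track] = field(default_factory=list)
    _next_id: int = 0

    def new_track(self, frame_index: int, det: Detection) -> Track:
        t = Track(id=self._next_id)
        self._next_id += 1
        t.append(frame_index, det)
        self.tracks.append(t)
        return t

    @property
    def live_tracks(self) -> list[Track]:
        return [t for t in self.tracks if t.status is not TrackStatus.TERMINATED]

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass
class AssignmentResult:
    pairs: list[tuple[int, int]]
    unmatched_rows: list[int]
    unmatched_cols: list[int]
    total_cost: float


def solve_assignment(
    cost: np.ndarray, unmatched_cost: float | None = None
) -> AssignmentResult:
    """Exact minimum-cost one-to-one assignment of rows to columns.

    With ``unmatched_cost`` set, the R x C rectangle is padded to an
    (R+C) square: every row and column gains a virtual partner at that
    cost (virtual-virtual pairs cost 0), so any real pairing more
    expensive than ``unmatched_cost`` — in particular gated-out entries
    at :data:`FORBIDDEN_COST` — resolves to non-assignment instead.
    Without it the rectangle is solved directly and the shorter side is
    fully matched.  ``total_cost`` sums the original matrix entries over
    the returned real pairs.
    """
    cost = np.asarray(cost, dtype=np.float64)
    if cost.size == 0:
        n_rows = cost.shape[0] if cost.ndim == 2 else 0
        n_cols = cost.shape[1] if cost.ndim == 2 else 0
        return AssignmentResult(
            pairs=[],
            unmatched_rows=list(range(n_rows)),
            unmatched_cols=list(range(n_cols)),
            total_cost=0.0,
        )
    if cost.ndim != 2:
        raise ValueError("cost must be a 2-D matrix")
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    n_rows, n_cols = cost.shape

    if unmatched_cost is None:
        rows, cols = linear_sum_assignment(cost)
        pairs = list(zip(rows.tolist(), cols.tolist()))
    else:
        n = n_rows + n_cols
        padded = np.zeros((n, n))
        padded[:n_rows, :n_cols] = cost
        padded[:n_rows, n_cols:] = FORBIDDEN_COST
        padded[n_rows:, :n_cols] = FORBIDDEN_COST
        padded[np.arange(n_rows), n_cols + np.arange(n_rows)] = unmatched_cost
        padded[n_rows + np.arange(n_cols), np.arange(n_cols)] = unmatched_cost
        rows, cols = linear_sum_assignment(padded)
        pairs = [
            (int(r), int(c))
            for r, c in zip(rows, cols)
            if r < n_rows and c < n_cols and cost[r, c] < FORBIDDEN_COST
        ]
    matched_rows = {r for r, _ in pairs}
    matched_cols = {c for _, c in pairs}
    return AssignmentResult(
        pairs=sorted(pairs),
        unmatched_rows=[r for r in range(n_rows) if r not in matched_rows],
        unmatched_cols=[c for c in range(n_cols) if c not in matched_cols],
        total_cost=float(sum(cost[r, c] for r, c in pairs)),
    )


def step_tracks(
    trackset: TrackSet,
    detections: Sequence[Detection],
    gate_px: float = DEFAULT_GATE_PX,
    max_misses: int = DEFAULT_MAX_MISSES,
) -> TrackSet:
    """Associate one frame's detections with the live tracks (in place).

    Pair costs are centroid distances; distances above ``gate_px`` are
    forbidden.  Matched tracks extend and reset their miss counter;
    unmatched tracks miss (lost, terminated when ``misses > max_misses``);
    unmatched detections found new tracks unconditionally.
    """
    if gate_px <= 0:
        raise ValueError("gate_px must be > 0")
    if max_misses < 0:
        raise ValueError("max_misses must be >= 0")
    frames = {d.frame_index for d in detections}
    if len(frames) > 1:
        raise ValueError(f"detections span multiple frames: {sorted(frames)}")
    frame_index = frames.pop() if frames else None

    live = trackset.live_tracks
    if live and detections:
        track_xy = np.array([t.last_centroid for t in live])
        det_xy = np.array([d.centroid_xy_px for d in detections])
        dist = np.linalg.norm(track_xy[:, None, :] - det_xy[None, :, :], axis=2)
        gated = np.where(dist <= gate_px, dist, FORBIDDEN_COST)
        result = solve_assignment(gated, unmatched_cost=gate_px)
    else:
        result = AssignmentResult(
            pairs=[],
            unmatched_rows=list(range(len(live))),
            unmatched_cols=list(range(len(detections))),
            total_cost=0.0,
        )

    for ti, di in result.pairs:
        live[ti].append(detections[di].frame_index, detections[di])
    for ti in result.unmatched_rows:
        t = live[ti]
        t.misses += 1
        t.status = (
            TrackStatus.TERMINATED if t.misses > max_misses else TrackStatus.LOST
        )
    for di in result.unmatched_cols:
        d = detections[di]
        trackset.new_track(d.frame_index, d)
    return trackset


def track_sequence(
    per_frame_detections: Sequence[Sequence[Detection]],
    gate_px: float = DEFAULT_GATE_PX,
    max_misses: int = DEFAULT_MAX_MISSES,
) -> TrackSet:
    """Track detections over a whole movie.

    Frame 0 detections each found a track; every later frame is linked
    with :func:`step_tracks`.  The returned TrackSet includes terminated
    tracks.
    """
    if len(per_frame_detections) < 1:
        raise ValueError("need at least one frame of detections")
    ts = TrackSet()
    for det in per_frame_detections[0]:
        ts.new_track(det.frame_index, det)
    for dets in per_frame_detections[1:]:
        step_tracks(ts, dets, gate_px=gate_px, max_misses=max_misses)
    return ts
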