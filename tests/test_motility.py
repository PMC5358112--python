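"""Movement vectors, wind-rose binning, regional time series."""

from __future__ import annotations

import numpy as np
import pytest

from membratrack.image_io import FrameStack, LabelMask
from membratrack.motility import (
    MotilityStep,
    compute_steps,
    net_displacements,
    region_time_series,
    windrose,
)
from membratrack.segmentation import Detection
from membratrack.tracking import Track, TrackSet


def _track(tid, obs):
    """obs: list of (frame, x, y)."""
    t = Track(id=tid)
    for f, x, y in obs:
        t.points.append(
            (f, Detection(frame_index=f, label=1, centroid_xy_px=(x, y), area_px2=1))
        )
    return t


def _vec(direction_deg, speed=1.0, tid=0):
    return MotilityStep(
        track_id=tid,
        t0=0,
        t1=1,
        displacement_um=(np.cos(np.radians(direction_deg)) * speed,
                         np.sin(np.radians(direction_deg)) * speed),
        speed_um_per_min=speed,
        direction_deg=direction_deg % 360.0,
    )


class TestComputeSteps:
    def test_axis_aligned_displacement(self):
        ts = TrackSet(tracks=[_track(0, [(0, 10, 10), (1, 12, 10)])])
        (step,) = compute_steps(ts, pixel_size_um=1.0, frame_interval_min=5.0)
        assert step.displacement_um == (2.0, 0.0)
        assert step.speed_um_per_min == pytest.approx(0.4)
        assert step.direction_deg == 0.0

    def test_upward_motion_is_90_degrees(self):
        # raster y decreases => cell moves up => mathematical +y
        ts = TrackSet(tracks=[_track(0, [(0, 10, 10), (1, 10, 8)])])
        (step,) = compute_steps(ts, 1.0, 5.0)
        assert step.displacement_um == (0.0, 2.0)
        assert step.direction_deg == 90.0

    def test_stationary_step_flagged_degenerate(self):
        ts = TrackSet(tracks=[_track(0, [(0, 5, 5), (1, 5, 5)])])
        (step,) = compute_steps(ts, 1.0, 5.0)
        assert step.speed_um_per_min == 0.0
        assert step.direction_deg == 0.0
        assert step.degenerate

    def test_bridged_gap_scales_elapsed_time(self):
        ts = TrackSet(tracks=[_track(0, [(0, 0, 0), (3, 6, 0)])])
        (step,) = compute_steps(ts, 1.0, 5.0)
        assert step.t1 - step.t0 == 3
        assert step.speed_um_per_min == pytest.approx(6 / 15)

    def test_step_count_is_observations_minus_one_per_track(self):
        ts = TrackSet(
            tracks=[
                _track(0, [(0, 0, 0), (1, 1, 0), (2, 2, 0)]),
                _track(1, [(0, 5, 5)]),
                _track(2, [(2, 1, 1), (3, 2, 2)]),
            ]
        )
        assert len(compute_steps(ts, 1.0, 5.0)) == 2 + 0 + 1

    def test_net_displacement_aggregates_whole_track(self):
        ts = TrackSet(tracks=[_track(0, [(0, 0, 0), (1, 3, 0), (2, 0, -4)])])
        (v,) = net_displacements(ts, 1.0, 5.0)
        assert v.displacement_um == (0.0, 4.0)
        assert v.direction_deg == 90.0


class TestWindrose:
    def test_uniform_cardinal_vectors(self):
        rose = windrose([_vec(d) for d in (0, 90, 180, 270)], n_sectors=4,
                        band_edges=[0.0])
        np.testing.assert_allclose(rose.proportions, [0.25] * 4)
        assert rose.n_vectors == 4

    def test_single_sector_band_split_matches_counting(self):
        # ten vectors at 5 deg, speeds straddling the 1.0 band edge
        speeds = [0.5] * 7 + [1.5] * 3
        vectors = [_vec(5.0, s) for s in speeds]
        rose = windrose(vectors, n_sectors=8, band_edges=[0.0, 1.0])
        assert rose.proportions[0] == pytest.approx(1.0)
        np.testing.assert_allclose(rose.band_fractions[0], [0.7, 0.3])
        assert np.all(rose.band_fractions[1:] == 0)

    def test_all_below_min_speed_gives_empty_rose(self):
        rose = windrose([_vec(0.0, 0.01)], min_speed=0.5)
        assert rose.empty
        assert rose.n_vectors == 0
        assert np.all(rose.proportions == 0)

    def test_sector_wraparound_centred_on_zero(self):
        # 359 deg falls in the first sector (centred on 0) with 16 sectors
        rose = windrose([_vec(359.0)], n_sectors=16, band_edges=[0.0])
        assert rose.proportions[0] == 1.0

    def test_proportions_and_band_sums(self):
        rng = np.random.default_rng(0)
        vectors = [
            _vec(float(rng.uniform(0, 360)), float(rng.uniform(0.01, 2.0)))
            for _ in range(200)
        ]
        rose = windrose(vectors, n_sectors=16, band_edges=[0.0, 0.5, 1.0, 1.5])
        assert rose.proportions.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(
            rose.band_fractions.sum(axis=1), rose.proportions, atol=1e-12
        )

    def test_degenerate_vectors_excluded(self):
        vectors = [_vec(0.0, 1.0)]
        stationary = MotilityStep(0, 0, 1, (0.0, 0.0), 0.0, 0.0, degenerate=True)
        rose = windrose(vectors + [stationary])
        assert rose.n_vectors == 1

    def test_validation(self):
        with pytest.raises(ValueError):
            windrose([], n_sectors=1)
        with pytest.raises(ValueError):
            windrose([], band_edges=[1.0, 0.5])


def _mask_with_cells(shape, centers, half=2):
    labels = np.zeros(shape, dtype=np.int64)
    for i, (x, y) in enumerate(centers, start=1):
        labels[y - half : y + half, x - half : x + half] = i
    return labels


class TestRegionTimeSeries:
    def _stack(self, n_frames, shape=(64, 64), px=2.0):
        return FrameStack(
            frames=[np.zeros(shape) for _ in range(n_frames)],
            pixel_size_um=px,
            frame_interval_min=5.0,
        )

    def test_direct_partition(self):
        centers = [(5, 10), (10, 20), (15, 30), (40, 10), (45, 20), (50, 30),
                   (55, 40), (40, 50)]
        labels = _mask_with_cells((64, 64), centers)
        series = region_time_series(
            [LabelMask(labels=labels)], self._stack(1), split_x_px=32.0
        )
        assert series.counts("left").tolist() == [3]
        assert series.counts("right").tolist() == [5]
        assert series.counts("all").tolist() == [8]

    def test_boundary_centroids_count_right(self):
        labels = _mask_with_cells((64, 64), [(32, 20)])  # centroid x = 31.5 + 0 ...
        # region spans columns 30..33 -> centroid exactly 31.5; use split there
        series = region_time_series(
            [LabelMask(labels=labels)], self._stack(1), split_x_px=31.5
        )
        assert series.counts("right").tolist() == [1]
        assert series.counts("left").tolist() == [0]

    def test_mean_area_in_square_micrometres(self):
        labels = _mask_with_cells((64, 64), [(10, 10)])  # 4x4 px cell
        series = region_time_series(
            [LabelMask(labels=labels)], self._stack(1, px=2.0), split_x_px=32.0
        )
        row = series.table[(series.table.region == "all") & (series.table.frame == 0)]
        assert row.mean_area_um2.iloc[0] == pytest.approx(16 * 4.0)

    def test_counts_invariant_under_relabelling(self):
        centers = [(10, 10), (20, 40), (50, 20), (40, 50)]
        labels = _mask_with_cells((64, 64), centers)
        permuted = np.zeros_like(labels)
        for old, new in zip([1, 2, 3, 4], [3, 1, 4, 2]):
            permuted[labels == old] = new
        a = region_time_series([LabelMask(labels=labels)], self._stack(1))
        b = region_time_series([LabelMask(labels=permuted)], self._stack(1))
        for region in ("left", "right", "all"):
            assert a.counts(region).tolist() == b.counts(region).tolist()

    def test_split_outside_field_rejected(self):
        with pytest.raises(ValueError, match="split"):
            region_time_series(
                [LabelMask(labels=np.zeros((8, 8), dtype=np.int64))],
                self._stack(1, shape=(8, 8)),
                split_x_px=100.0,
            )

    def test_global_drift_moves_modal_sector(self):
        # synthetic tracks drifting along +x must put the modal spoke at 0 deg
        rng = np.random.default_rng(5)
        tracks = []
        for i in range(30):
            x0, y0 = rng.uniform(10, 50, size=2)
            obs = [(t, x0 + 2.0 * t + rng.normal(0, 0.2),
                    y0 + rng.normal(0, 0.2)) for t in range(5)]
            tracks.append(_track(i, obs))
        ts = TrackSet(tracks=tracks)
        rose = windrose(net_displacements(ts, 1.0, 5.0))
        assert rose.modal_sector_center_deg == 0.0
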