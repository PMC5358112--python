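"""h-minima transform, marker extraction, watershed, per-cell measurement."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from membratrack.image_io import LabelMask
from membratrack.segmentation import (
    Detection,
    SegmentationParams,
    extract_detections,
    extract_markers,
    segment_frame,
    suppress_minima,
    watershed_segment,
)
from membratrack.synthetic import SceneParams, generate_scene

from oracles import hminima_by_iteration, regional_minima_by_flood, watershed_by_linear_scan


class TestSuppressMinima:
    def test_h_zero_is_identity(self):
        rng = np.random.default_rng(0)
        relief = rng.uniform(0, 10, (8, 8))
        np.testing.assert_array_equal(suppress_minima(relief, 0.0), relief)

    def test_one_dimensional_example(self):
        # depth-3 minimum is raised by h, depth-1 minimum is annihilated
        relief = np.array([[5.0, 2.0, 5.0, 4.0, 5.0]])
        out = suppress_minima(relief, 2.0)
        np.testing.assert_array_equal(out, [[5.0, 4.0, 5.0, 5.0, 5.0]])

    def test_matches_iterative_reconstruction_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            relief = rng.integers(0, 256, size=(12, 12)).astype(np.float64)
            h = float(rng.integers(1, 21))
            np.testing.assert_array_equal(
                suppress_minima(relief, h), hminima_by_iteration(relief, h)
            )

    def test_output_bounded_by_relief_and_relief_plus_h(self):
        rng = np.random.default_rng(2)
        relief = rng.integers(0, 256, size=(16, 16)).astype(np.float64)
        h = 7.0
        out = suppress_minima(relief, h)
        assert np.all(out >= relief)
        assert np.all(out <= relief + h)

    def test_shallow_minima_annihilated_deep_minima_kept(self):
        # a depth-10 pit survives (raised by h); a depth-3 pit vanishes
        relief = np.full((1, 9), 10.0)
        relief[0, 2] = 0.0
        relief[0, 6] = 7.0
        out = suppress_minima(relief, 5.0)
        np.testing.assert_array_equal(out, [[10, 10, 5, 10, 10, 10, 10, 10, 10]])

    def test_negative_h_rejected(self):
        with pytest.raises(ValueError):
            suppress_minima(np.zeros((4, 4)), -1.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        relief=arrays(np.int64, (7, 7), elements=st.integers(0, 40)),
        h=st.integers(0, 15),
    )
    def test_property_bounds_and_oracle_agreement(self, relief, h):
        relief = relief.astype(np.float64)
        out = suppress_minima(relief, float(h))
        assert np.all(out >= relief)
        assert np.all(out <= relief + h)
        np.testing.assert_array_equal(out, hminima_by_iteration(relief, float(h)))


class TestExtractMarkers:
    def test_constant_relief_single_marker(self):
        markers = extract_markers(np.full((6, 6), 3.0))
        assert markers.n_labels == 1
        assert np.all(markers.labels == 1)

    def test_two_basins(self):
        relief = np.ones((5, 7))
        relief[2, 1] = 0.0
        relief[2, 5] = 0.0
        markers = extract_markers(relief)
        assert markers.n_labels == 2
        # raster-order labelling: left basin first
        assert markers.labels[2, 1] == 1
        assert markers.labels[2, 5] == 2

    def test_matches_flood_definition_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            relief = rng.integers(0, 6, size=(9, 9)).astype(np.float64)
            markers = extract_markers(relief)
            np.testing.assert_array_equal(
                markers.labels > 0, regional_minima_by_flood(relief)
            )


class TestWatershedSegment:
    def test_uniform_relief_symmetric_split(self):
        relief = np.zeros((5, 8))
        markers = np.zeros((5, 8), dtype=np.int64)
        markers[2, 1] = 1
        markers[2, 6] = 2
        out = watershed_segment(relief, LabelMask(labels=markers))
        # split along the equidistant line; on uniform relief the flood
        # claims by (label, raster) so the left half is 1, right half 2
        assert np.all(out.labels[:, :4] == 1)
        assert np.all(out.labels[:, 4:][out.labels[:, 4:] > 0] == 2)

    def test_central_ridge_splits_labels(self):
        relief = np.zeros((5, 5))
        relief[:, 2] = 10.0  # high ridge column
        markers = np.zeros((5, 5), dtype=np.int64)
        markers[2, 0] = 1
        markers[2, 4] = 2
        out = watershed_segment(relief, LabelMask(labels=markers))
        assert np.all(out.labels[:, :2] == 1)
        assert np.all(out.labels[:, 3:] == 2)

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            relief = rng.integers(0, 10, size=(8, 8)).astype(np.float64)
            k = int(rng.integers(2, 5))
            markers = np.zeros((8, 8), dtype=np.int64)
            flat = rng.choice(64, size=k, replace=False)
            for i, f in enumerate(flat):
                markers[divmod(f, 8)] = i + 1
            ours = watershed_segment(relief, LabelMask(labels=markers))
            np.testing.assert_array_equal(
                ours.labels, watershed_by_linear_scan(relief, markers)
            )

    def test_region_count_equals_marker_count_and_partition(self):
        rng = np.random.default_rng(5)
        relief = rng.uniform(0, 1, (12, 12))
        markers = np.zeros((12, 12), dtype=np.int64)
        markers[2, 2], markers[9, 3], markers[5, 10] = 1, 2, 3
        out = watershed_segment(relief, LabelMask(labels=markers))
        assert set(np.unique(out.labels)) == {1, 2, 3}

    def test_zero_markers_rejected(self):
        with pytest.raises(ValueError, match="marker"):
            watershed_segment(np.zeros((4, 4)), LabelMask(labels=np.zeros((4, 4), dtype=np.int64)))


class TestSegmentFrame:
    def test_recovers_synthetic_epithelium(self, static_scene49):
        from membratrack.synthetic import evaluate_segmentation

        frame = static_scene49.frames.frames[0]
        mask = segment_frame(frame)
        assert mask.n_labels == 49
        score = evaluate_segmentation([mask], [static_scene49.gt_masks[0]])
        assert score.mean_iou >= 0.9

    def test_blank_frame_single_region(self):
        mask = segment_frame(np.zeros((32, 32)))
        assert mask.n_labels == 1
        assert np.all(mask.labels == 1)

    def test_doubling_h_never_increases_region_count(self, noisy_scene49):
        frame = noisy_scene49.frames.frames[0]
        counts = [
            segment_frame(frame, SegmentationParams(h_rel=h)).n_labels
            for h in (0.02, 0.04, 0.08, 0.16)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_deterministic(self, small_scene):
        frame = small_scene.frames.frames[0]
        a = segment_frame(frame)
        b = segment_frame(frame)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_consecutive_and_areas_tile_field(self, small_scene):
        frame = small_scene.frames.frames[0]
        mask = segment_frame(frame)
        vals = np.unique(mask.labels)
        assert vals[0] >= 1  # watershed lines absorbed: no 0 background
        assert list(vals) == list(range(vals[0], vals[-1] + 1))
        dets = extract_detections(mask, frame)
        assert sum(d.area_px2 for d in dets) == mask.labels.size


class TestExtractDetections:
    def test_square_region(self):
        labels = np.zeros((4, 4), dtype=np.int64)
        labels[1:3, 1:3] = 1
        dets = extract_detections(LabelMask(labels=labels), np.ones((4, 4)))
        assert len(dets) == 1
        assert dets[0].centroid_xy_px == (1.5, 1.5)
        assert dets[0].area_px2 == 4

    def test_l_shaped_region_pixel_mean(self):
        labels = np.zeros((3, 3), dtype=np.int64)
        labels[0, 0] = labels[0, 1] = labels[1, 1] = 1
        # pixels (x, y): (0,0), (1,0), (1,1) -> mean (2/3, 1/3)
        dets = extract_detections(LabelMask(labels=labels), np.zeros((3, 3)))
        np.testing.assert_allclose(dets[0].centroid_xy_px, (2 / 3, 1 / 3))
        assert dets[0].area_px2 == 3

    def test_empty_mask(self):
        dets = extract_detections(
            LabelMask(labels=np.zeros((4, 4), dtype=np.int64)), np.zeros((4, 4))
        )
        assert dets == []

    def test_centroid_inside_bounding_box_and_sorted(self):
        rng = np.random.default_rng(6)
        labels = (rng.uniform(size=(20, 20)) < 0.5).astype(np.int64)
        from scipy import ndimage as ndi

        labels, _ = ndi.label(labels)
        dets = extract_detections(LabelMask(labels=labels), rng.uniform(size=(20, 20)))
        assert [d.label for d in dets] == sorted(d.label for d in dets)
        for d in dets:
            ys, xs = np.nonzero(labels == d.label)
            x, y = d.centroid_xy_px
            assert xs.min() <= x <= xs.max()
            assert ys.min() <= y <= ys.max()
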