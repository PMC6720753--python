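"""Thresholding, cleanup, thinning and finger ROI extraction."""

import warnings

import numpy as np
import pytest
from skimage import measure

from handtherm import preprocessing as pp
from handtherm import segmentation as seg
from handtherm import synthetic as syn
from handtherm.pipeline import process_sequence
from tests.conftest import FINGER_INDEX, point_in_capsule, point_in_palm


def _grey(arr):
    return pp.GreyImage(data=np.asarray(arr, dtype=np.uint8), t_min=20.0,
                        t_max=40.0)


class TestBhtThreshold:
    def test_symmetric_bimodal_histogram_balances_at_midpoint(self):
        hist = np.zeros(256, dtype=int)
        hist[100] = 500
        hist[156] = 500
        assert seg.bht_threshold(hist) == 128

    def test_unbalanced_spikes_threshold_strictly_between_modes(self):
        # 900 pixels at level 50, 100 pixels at level 200: trimming the
        # heavier left side drags the midpoint toward the lighter mode
        hist = np.zeros(256, dtype=int)
        hist[50] = 900
        hist[200] = 100
        level = seg.bht_threshold(hist)
        assert level == 125
        assert 50 < level < 200

    def test_gaussian_mixture_separates_classes_exactly(self):
        rng = np.random.default_rng(12)
        bg = np.clip(np.round(rng.normal(60, 8, 6000)), 0, 255).astype(int)
        fg = np.clip(np.round(rng.normal(180, 10, 3000)), 0, 255).astype(int)
        hist = np.bincount(np.concatenate([bg, fg]), minlength=256)
        level = seg.bht_threshold(hist)
        # the BHT level must fall inside the empty valley, so thresholding
        # misclassifies no pixel of either class
        assert bg.max() <= level < fg.min()
        misclassified = (bg > level).sum() + (fg <= level).sum()
        assert misclassified == 0

    def test_unimodal_histogram_raises_no_clear_border(self):
        rng = np.random.default_rng(13)
        draws = np.clip(np.round(rng.normal(90, 6, 5000)), 0, 255).astype(int)
        hist = np.bincount(draws, minlength=256)
        with pytest.raises(seg.NoClearBorderError):
            seg.bht_threshold(hist)

    def test_single_level_histogram_raises(self):
        hist = np.zeros(256, dtype=int)
        hist[77] = 1000
        with pytest.raises(seg.NoClearBorderError):
            seg.bht_threshold(hist)

    def test_wrong_bin_count_rejected(self):
        with pytest.raises(ValueError):
            seg.bht_threshold(np.ones(100, dtype=int))


class TestFrameDifference:
    def test_identical_frames_give_empty_mask_with_warning(self):
        img = _grey(np.full((20, 20), 90))
        with pytest.warns(UserWarning, match="identical"):
            mask = seg.frame_difference_threshold(img, img)
        assert not mask.data.any()
        assert mask.method == "frame-difference"

    def test_changed_region_recovered_exactly(self):
        a = np.full((30, 30), 40, dtype=np.uint8)
        b = a.copy()
        truth = np.zeros((30, 30), dtype=bool)
        truth[8:22, 10:20] = True
        b[truth] = 120  # the "hand" warms by 80 grey levels
        mask = seg.frame_difference_threshold(_grey(a), _grey(b))
        assert np.array_equal(mask.data, truth)

    def test_robust_to_small_background_flicker(self):
        rng = np.random.default_rng(21)
        a = rng.integers(38, 43, size=(40, 40)).astype(np.uint8)
        b = np.clip(a.astype(int) + rng.integers(-2, 3, size=(40, 40)),
                    0, 255).astype(np.uint8)
        truth = np.zeros((40, 40), dtype=bool)
        truth[10:30, 12:28] = True
        b[truth] = 140
        mask = seg.frame_difference_threshold(_grey(a), _grey(b))
        disagreement = (mask.data != truth).mean()
        assert disagreement < 0.01

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg.frame_difference_threshold(_grey(np.zeros((5, 5))),
                                           _grey(np.zeros((6, 5))))


class TestMorphologicalCleanup:
    def _mask(self, data):
        return seg.BinaryMask(data=np.asarray(data, bool), threshold=0,
                              method="histogram")

    def test_clean_rectangle_is_fixed_point(self):
        data = np.zeros((30, 30), dtype=bool)
        data[5:25, 5:25] = True
        cleaned, converged = seg.morphological_cleanup(self._mask(data))
        assert converged
        assert np.array_equal(cleaned.data, data)

    def test_isolated_speckles_removed(self):
        data = np.zeros((40, 40), dtype=bool)
        data[10:30, 10:30] = True
        rng = np.random.default_rng(31)
        for r, c in rng.integers(0, 40, size=(15, 2)):
            if not (8 <= r < 32 and 8 <= c < 32):
                data[r, c] = True
        cleaned, converged = seg.morphological_cleanup(self._mask(data))
        assert converged
        assert measure.label(cleaned.data, connectivity=2).max() == 1
        assert cleaned.data[10:30, 10:30].all()

    def test_one_pixel_hole_filled_by_closing(self):
        data = np.zeros((30, 30), dtype=bool)
        data[5:25, 5:25] = True
        data[15, 15] = False
        cleaned, converged = seg.morphological_cleanup(self._mask(data))
        assert converged
        assert cleaned.data[15, 15]

    def test_empty_mask_converges_immediately(self):
        cleaned, converged = seg.morphological_cleanup(
            self._mask(np.zeros((10, 10), dtype=bool)))
        assert converged
        assert not cleaned.data.any()


class TestSkeletonize:
    def test_horizontal_bar_reduces_to_thin_midline(self):
        data = np.zeros((10, 34), dtype=bool)
        data[3:6, 2:32] = True  # 3-pixel-thick, 30-pixel-long bar
        skel = seg.skeletonize(data).data
        rows = set(np.nonzero(skel)[0].tolist())
        assert rows <= {3, 4, 5}
        # one pixel per column along the retained length
        cols = np.nonzero(skel)[1]
        assert len(cols) == len(set(cols.tolist()))
        assert skel.sum() >= 25  # retains most of the bar's length

    def test_disc_collapses_to_near_point(self):
        rr, cc = np.mgrid[0:21, 0:21]
        disc = (rr - 10) ** 2 + (cc - 10) ** 2 <= 64
        skel = seg.skeletonize(disc).data
        assert 1 <= skel.sum() <= 3
        assert skel[8:13, 8:13].any()

    def test_skeleton_is_subset_and_thin(self, we_md_processed):
        _, segres = we_md_processed
        skel = segres.skeleton.data
        assert not (skel & ~segres.mask.data).any()
        # thinness: no 2x2 block entirely on the skeleton
        blocks = (skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:])
        assert not blocks.any()

    def test_empty_input_yields_empty_skeleton(self):
        assert not seg.skeletonize(np.zeros((5, 5), dtype=bool)).data.any()


class TestIdentifyFingers:
    _DIRECTIONS = ((0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1))

    def _star(self, arms=5, length=20):
        """Synthetic skeleton: exact unit-step arms radiating from a centre,
        thumb→little ordered left → up-left → up → up-right → right."""
        size = 2 * length + 11
        data = np.zeros((size, size), dtype=bool)
        centre = size // 2
        for dr, dc in self._DIRECTIONS[:arms]:
            for step in range(length + 1):
                data[centre + step * dr, centre + step * dc] = True
        return seg.Skeleton(data=data)

    def test_five_arm_star_yields_five_ordered_fingers(self):
        length = 20
        skel = self._star(length=length)
        centre = skel.data.shape[0] // 2
        rois = seg.identify_fingers(skel, min_length=8, junction_clearance=0)
        assert [r.label for r in rois] == list(syn.FINGER_LABELS)
        expected_tips = [(centre + length * dr, centre + length * dc)
                         for dr, dc in self._DIRECTIONS]
        assert [tuple(map(int, r.path[0])) for r in rois] == expected_tips

    def test_paths_are_8_connected_from_fingertip(self):
        for roi in seg.identify_fingers(self._star(), min_length=8):
            for (r1, c1), (r2, c2) in zip(roi.path, roi.path[1:]):
                assert max(abs(r1 - r2), abs(c1 - c2)) == 1

    def test_short_spurs_excluded_by_min_length(self):
        skel = self._star()
        data = skel.data.copy()
        centre = data.shape[0] // 2
        # 4-pixel spur branching off the middle of the "up" arm
        for k in range(1, 5):
            data[centre - 10, centre + k] = True
        rois = seg.identify_fingers(seg.Skeleton(data=data), min_length=8)
        assert len(rois) == 5
        assert all(r.length >= 8 for r in rois)
        spur_pixels = {(centre - 10, centre + k) for k in range(1, 5)}
        assert all(spur_pixels.isdisjoint(map(tuple, r.path)) for r in rois)

    def test_four_arms_raise_segmentation_error(self):
        with pytest.raises(seg.SegmentationError, match="expected 5"):
            seg.identify_fingers(self._star(arms=4), min_length=8)

    def test_junction_clearance_shortens_but_keeps_fingertip(self):
        full = seg.identify_fingers(self._star(), min_length=8,
                                    junction_clearance=0)
        trimmed = seg.identify_fingers(self._star(), min_length=8,
                                       junction_clearance=4)
        for a, b in zip(full, trimmed):
            assert b.path[0] == a.path[0]
            # clearance trims up to 4 junction-side pixels but never below
            # the minimum branch length
            assert b.length == max(8, a.length - 4)
            assert b.length < a.length


class TestSegmentHandEndToEnd:
    def test_mask_tightly_covers_rasterized_truth(self, geometry,
                                                  we_md_processed):
        from scipy import ndimage

        _, segres = we_md_processed
        truth = syn.render_hand_mask(geometry)
        mask = segres.mask.data
        # smoothing bleeds warmth into a thin halo and closing fills the
        # finger-junction notches, so the mask is a superset of the truth
        # confined to a 2-pixel band around it
        assert (truth & ~mask).sum() == 0
        assert not (mask & ~ndimage.binary_dilation(truth, iterations=2)).any()
        jaccard = (mask & truth).sum() / (mask | truth).sum()
        assert jaccard > 0.95
        assert segres.mask.method == "histogram"
        assert not segres.fallback_used
        assert segres.restarts == 0

    def test_every_roi_pixel_lies_in_its_own_finger(self, geometry,
                                                    we_md_processed):
        _, segres = we_md_processed
        for roi in segres.rois:
            finger = geometry.fingers[FINGER_INDEX[roi.label]]
            for r, c in roi.path:
                # finger capsules take rendering precedence over the palm,
                # so own-capsule membership guarantees the pixel carries its
                # finger's temperature even where a base overlaps the palm
                assert point_in_capsule(finger, r, c), (roi.label, r, c)
            tip = roi.path[0]
            assert not point_in_palm(geometry, *tip)

    def test_roi_lengths_cover_most_of_each_finger(self, geometry,
                                                   we_md_processed):
        _, segres = we_md_processed
        for roi in segres.rois:
            finger = geometry.fingers[FINGER_INDEX[roi.label]]
            # midline should span at least half the capsule's axis length
            assert roi.length >= finger.length / 2

    def test_skeleton_endpoint_census(self, geometry, we_md_processed):
        """Five endpoints in fingers (the tips) and at least one in the palm."""
        _, segres = we_md_processed
        degree = seg._degree_map(segres.skeleton.data)
        endpoints = [tuple(p) for p in np.argwhere(degree == 1)]
        in_finger = [e for e in endpoints
                     if any(point_in_capsule(f, *e) for f in geometry.fingers)
                     and not point_in_palm(geometry, *e)]
        in_palm = [e for e in endpoints if point_in_palm(geometry, *e)]
        assert len(in_finger) == 5
        assert len(in_palm) >= 1

    def test_low_contrast_scene_uses_frame_difference_fallback(self, geometry):
        from dataclasses import replace

        subject = syn.subject_from_preset("moderate")
        # ambient pushed against skin temperature: histogram modes merge
        thermal = replace(subject.thermal, ambient=31.9)
        sequence = syn.simulate_sequence(replace(subject, thermal=thermal),
                                         geometry)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics, segres = process_sequence(sequence)
        assert segres.fallback_used
        assert len(segres.rois) == 5
        assert metrics.hand_mean["dt_c"] == pytest.approx(
            subject.thermal.delta_tc, abs=0.05)

    def test_unsegmentable_scene_reports_both_routes(self):
        flat = _grey(np.full((60, 60), 120))
        with pytest.raises(seg.SegmentationError, match="all routes"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")
            seg.segment_hand(flat, flat)

    def test_segmentation_is_deterministic(self, we_md_sequence):
        a = process_sequence(we_md_sequence)[1]
        b = process_sequence(we_md_sequence)[1]
        assert np.array_equal(a.mask.data, b.mask.data)
        assert [r.path for r in a.rois] == [r.path for r in b.rois]
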