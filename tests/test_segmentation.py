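"""Watershed segmentation, marker seeding, the 3 mm gate, and centering."""

import numpy as np
import pytest

from conftest import disc_image, two_disc_image
from dbmca.io import CTImage, PixelSpacing
from dbmca.segmentation import (
    center_on_mask,
    compute_markers,
    gate_regions,
    segment_image,
    watershed_segment,
)


class TestMarkers:
    def test_background_only_slice_has_no_markers(self):
        rng = np.random.default_rng(0)
        img = CTImage(pixels=0.2 + 0.02 * rng.standard_normal((64, 64)),
                      spacing=PixelSpacing(1, 1))
        assert compute_markers(img).max() == 0

    def test_constant_slice_has_no_markers(self):
        img = CTImage(pixels=np.full((64, 64), 0.3), spacing=PixelSpacing(1, 1))
        assert compute_markers(img).max() == 0

    def test_two_separated_discs_two_markers(self):
        # oracle: two thresholded connected components
        img = two_disc_image(r1=12, r2=12, c1=(40, 40), c2=(40, 80))
        markers = compute_markers(img, min_distance_px=10)
        assert len(np.unique(markers)) - 1 == 2

    def test_single_disc_marker_at_centroid(self):
        # distance-transform argmax of a disc is its center (+-1 px)
        img = disc_image(radius=15, center=(60, 70))
        markers = compute_markers(img)
        pos = np.argwhere(markers > 0)
        assert len(pos) == 1
        assert abs(pos[0][0] - 60) <= 1 and abs(pos[0][1] - 70) <= 1


class TestWatershed:
    def test_two_discs_recovered_within_5pct_symmetric_difference(self):
        img = two_disc_image(r1=14, r2=10, c1=(40, 40), c2=(80, 85))
        markers = compute_markers(img)
        labels = watershed_segment(img, markers)
        truth = [
            (np.mgrid[0:128, 0:128][0] - 40) ** 2 + (np.mgrid[0:128, 0:128][1] - 40) ** 2 <= 14**2,
            (np.mgrid[0:128, 0:128][0] - 80) ** 2 + (np.mgrid[0:128, 0:128][1] - 85) ** 2 <= 10**2,
        ]
        found = [labels == lab for lab in np.unique(labels) if lab != 0]
        assert len(found) == 2
        for t in truth:
            best = min(np.logical_xor(t, f).sum() / t.sum() for f in found)
            assert best < 0.05

    def test_zero_markers_all_background(self):
        img = disc_image(radius=10)
        labels = watershed_segment(img, np.zeros((128, 128), dtype=np.int32))
        assert (labels == 0).all()

    def test_label_conservation(self):
        img = two_disc_image()
        markers = compute_markers(img)
        labels = watershed_segment(img, markers)
        assert set(np.unique(labels)) <= set(np.unique(markers)) | {0}
        # every marker pixel keeps its label
        pos = markers > 0
        assert np.array_equal(labels[pos], markers[pos])

    def test_shape_mismatch_rejected(self):
        img = disc_image(radius=10)
        with pytest.raises(ValueError):
            watershed_segment(img, np.zeros((64, 64), dtype=np.int32))


class TestGate:
    def _label_disc(self, radius_px, size=128):
        rows, cols = np.mgrid[0:size, 0:size]
        return ((rows - 64) ** 2 + (cols - 64) ** 2 <= radius_px**2).astype(np.int32)

    def test_below_threshold_excluded(self):
        # 2.5 mm equivalent diameter at 1 mm/px
        labels = self._label_disc(1.25)
        regions, mask = gate_regions(labels, PixelSpacing(1, 1), 3.0)
        assert regions == [] and mask.pixels.sum() == 0

    def test_exactly_3mm_retained_inclusive(self):
        # build a region whose pixel count gives exactly d = 3.0 mm:
        # area = pi * (1.5)^2 -> 7.068..; use 8 px -> d = 3.19; instead
        # construct d == 3.0 exactly: area A with 1*sqrt(4A/pi) == 3.0
        # -> A = 7.0686; not integer, so craft spacing to land exactly on 3.0
        area = 9
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:13, 10:13] = 1  # 3x3 block, 9 px
        d_px = np.sqrt(4 * area / np.pi)
        spacing = 3.0 / d_px  # makes equivalent diameter exactly 3.0 mm
        regions, mask = gate_regions(labels, PixelSpacing(spacing, spacing), 3.0)
        assert len(regions) == 1
        assert regions[0].equivalent_diameter_mm == pytest.approx(3.0, abs=1e-12)

    def test_mixed_sizes_one_survivor(self):
        # 2 mm and 6 mm discs at 1 mm/px: d = spacing*sqrt(4A/pi)
        rows, cols = np.mgrid[0:128, 0:128]
        labels = np.zeros((128, 128), dtype=np.int32)
        labels[(rows - 30) ** 2 + (cols - 30) ** 2 <= 1.0**2] = 1  # ~2 mm
        labels[(rows - 90) ** 2 + (cols - 90) ** 2 <= 3.0**2] = 2  # ~6 mm
        regions, _ = gate_regions(labels, PixelSpacing(1, 1), 3.0)
        assert len(regions) == 1 and regions[0].region_id == 2

    def test_gate_monotone_in_threshold(self):
        img = two_disc_image(r1=14, r2=4, c1=(40, 40), c2=(90, 90))
        markers = compute_markers(img)
        labels = watershed_segment(img, markers)
        counts = [len(gate_regions(labels, PixelSpacing(1, 1), t)[0])
                  for t in (1.0, 5.0, 10.0, 25.0, 40.0)]
        assert counts == sorted(counts, reverse=True)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            PixelSpacing(0.0, 1.0)


class TestCentering:
    def test_mask_centroid_moves_to_grid_center(self):
        img = disc_image(radius=8, center=(30, 90))
        _, regions, mask = segment_image(img)
        ci, cm = center_on_mask(img.pixels, mask.pixels)
        coords = np.argwhere(cm > 0)
        assert abs(coords[:, 0].mean() - 63.5) <= 1.0
        assert abs(coords[:, 1].mean() - 63.5) <= 1.0
        assert cm.sum() == mask.pixels.sum()  # mask content preserved

    def test_empty_mask_unchanged(self):
        img = np.random.default_rng(0).random((32, 32))
        ci, cm = center_on_mask(img, np.zeros((32, 32), dtype=np.uint8))
        assert np.array_equal(ci, img) and cm.sum() == 0
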