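"""Organoid live/dead cytometry: dual-engine detection and per-spheroid stats."""

import numpy as np
import pytest
from skimage import draw

from spheroquant.errors import ValidationError
from spheroquant.frames import ImageFrame, ImageStack
from spheroquant.organoid import (
    detect_dead_cells,
    detect_live_cells,
    detect_spheroids,
    max_projection,
    spheroid_stats,
)
from spheroquant.phantoms import make_organoid_field

from conftest import frame_from

PX = 1.6  # µm/px used throughout


def noise_free_field(seed=0, **kw):
    return make_organoid_field(seed=seed, noise_sd=0, poisson=False, **kw)


def match_counts(points, planted_xy, tol_um=12.0):
    """Greedy one-to-one matching of detections to planted points."""
    used = set()
    hits = 0
    for x, y in planted_xy:
        best = None
        best_d = tol_um
        for i, p in enumerate(points):
            if i in used:
                continue
            d = np.hypot(x - p[0], y - p[1])
            if d <= best_d:
                best, best_d = i, d
        if best is not None:
            used.add(best)
            hits += 1
    return hits, len(points) - len(used)


class TestDeadCells:
    def test_blank_channel(self):
        det = detect_dead_cells(frame_from(np.zeros((64, 64)), PX), cell_diameter=12)
        assert det.count == 0 and not det.mask.any()

    def test_planted_dots_recovered_exactly(self):
        (_, orange), truth = noise_free_field(seed=1)
        det = detect_dead_cells(orange, cell_diameter=12)
        planted = [xy for s in truth.objects["spheroids"] for xy in s["dead_xy_um"]]
        hits, false_pos = match_counts(det.points, planted)
        assert hits == len(planted)
        assert false_pos == 0

    def test_final_mask_contains_both_engines(self):
        (_, orange), _ = noise_free_field(seed=2)
        det = detect_dead_cells(orange, cell_diameter=12)
        assert (det.mask & det.engine1_mask).sum() == det.engine1_mask.sum()
        assert (det.mask & det.engine2_mask).sum() == det.engine2_mask.sum()

    def test_too_small_diameter_rejected(self):
        with pytest.raises(ValidationError):
            detect_dead_cells(frame_from(np.zeros((8, 8)), PX), cell_diameter=2.0)


class TestLiveCells:
    def test_blank_channel(self):
        det = detect_live_cells(frame_from(np.zeros((64, 64)), PX), cell_diameter=12)
        assert det.count == 0

    def test_planted_puncta_recovered_exactly(self):
        (green, _), truth = noise_free_field(seed=3)
        det = detect_live_cells(green, cell_diameter=12)
        planted = [xy for s in truth.objects["spheroids"] for xy in s["live_xy_um"]]
        hits, false_pos = match_counts(det.points, planted)
        assert hits == len(planted) and false_pos == 0

    def test_count_nonincreasing_in_threshold(self):
        """On separated puncta, raising the threshold can only lose detections."""
        # dead channel: puncta only, so components never merge between levels
        (_, orange), _ = noise_free_field(seed=4)
        counts = [
            detect_live_cells(orange, 12, intensity_thresh=t).count
            for t in (0.3, 0.5, 0.7, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > 0


class TestSpheroids:
    def make_disc_field(self, radii_px):
        img = np.full((256, 256), 100.0)
        centres = [(y, x) for y in (50, 128, 206) for x in (50, 128, 206)]
        for (y, x), r in zip(centres, radii_px):
            rr, cc = draw.disk((y, x), r, shape=img.shape)
            img[rr, cc] = 500.0
        return frame_from(img, PX)

    def test_double_threshold_on_intensity_and_area(self):
        # 5 discs above min_area, 3 below
        big, small = 20, 4
        frame = self.make_disc_field([big] * 5 + [small] * 3)
        min_area = np.pi * (10 * PX) ** 2  # between the two sizes
        labels = detect_spheroids(frame, 0.5, min_area=min_area)
        assert labels.max() == 5

    def test_uniform_background_yields_none(self):
        frame = frame_from(np.full((64, 64), 100.0), PX)
        labels = detect_spheroids(frame, 200.0, min_area=10, relative=False)
        assert labels.max() == 0

    def test_zero_min_area_is_filter_identity(self):
        frame = self.make_disc_field([20, 4, 8])
        assert detect_spheroids(frame, 0.5, min_area=0).max() == 3

    def test_count_invariant_to_intensity_rescaling(self):
        frame = self.make_disc_field([20, 12])
        scaled = frame_from(frame.pixels * 2.0, PX)
        k1 = detect_spheroids(frame, 0.5, min_area=100).max()
        k2 = detect_spheroids(scaled, 0.5, min_area=100).max()
        assert k1 == k2 == 2


class TestSpheroidStats:
    def test_empty_label_mask(self):
        blank = frame_from(np.zeros((32, 32)), PX)
        live = detect_live_cells(blank, 12)
        dead = detect_dead_cells(blank, 12)
        records, summary = spheroid_stats(
            np.zeros((32, 32), int), live, dead, blank, blank, PX
        )
        assert records == [] and summary["spheroid_count"] == 0

    def test_per_spheroid_counts_exact_noise_free(self):
        (green, orange), truth = noise_free_field(seed=5)
        live = detect_live_cells(green, 12)
        dead = detect_dead_cells(orange, 12)
        labels = detect_spheroids(green, 0.25, min_area=np.pi * 18**2)
        records, summary = spheroid_stats(labels, live, dead, green, orange, PX)
        assert summary["spheroid_count"] == truth.objects["n_spheroids"]
        by_id = {r.spheroid_id: r for r in records}
        for s in truth.objects["spheroids"]:
            x, y = s["center_xy_um"]
            lab = labels[int(round(y / PX)), int(round(x / PX))]
            assert lab > 0
            assert by_id[lab].live_count == len(s["live_xy_um"])
            assert by_id[lab].dead_count == len(s["dead_xy_um"])

    def test_live_counts_bounded_by_total_detections(self):
        (green, orange), _ = noise_free_field(seed=6)
        live = detect_live_cells(green, 12)
        dead = detect_dead_cells(orange, 12)
        labels = detect_spheroids(green, 0.25, min_area=np.pi * 18**2)
        records, _ = spheroid_stats(labels, live, dead, green, orange, PX)
        assert sum(r.live_count for r in records) <= live.count

    def test_mismatched_geometry_rejected(self):
        a = frame_from(np.zeros((16, 16)), PX)
        b = frame_from(np.zeros((8, 8)), PX)
        live = detect_live_cells(a, 12)
        with pytest.raises(ValidationError):
            spheroid_stats(np.zeros((8, 8), int), live, live, a, b, PX)


class TestMaxProjection:
    def test_single_frame_identity(self):
        f = frame_from(np.arange(64, dtype=np.uint16).reshape(8, 8))
        out = max_projection(ImageStack([f], axis="z"))
        np.testing.assert_array_equal(out.pixels, f.pixels)

    def test_disjoint_spots_both_present(self):
        a = np.zeros((16, 16), np.uint16)
        b = np.zeros((16, 16), np.uint16)
        a[2, 2] = 900
        b[10, 10] = 700
        out = max_projection(ImageStack([frame_from(a), frame_from(b)], axis="z"))
        assert out.pixels[2, 2] == 900 and out.pixels[10, 10] == 700

    def test_matches_elementwise_oracle(self, rng):
        stack = ImageStack(
            [frame_from(rng.integers(0, 65535, (16, 16), dtype=np.uint16)) for _ in range(3)],
            axis="z",
        )
        np.testing.assert_array_equal(
            max_projection(stack).pixels, stack.as_array().max(axis=0)
        )

    def test_time_axis_rejected(self):
        stack = ImageStack([frame_from(np.zeros((8, 8)))], axis="t")
        with pytest.raises(ValidationError):
            max_projection(stack)
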