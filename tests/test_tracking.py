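"""Spot detection, optimal linking with gap closing, morphometry, confluence."""

import itertools

import numpy as np
import pytest
from skimage import draw

from spheroquant.errors import ValidationError
from spheroquant.phantoms import make_track_movie
from spheroquant.tracking import (
    Track,
    _gated_assignment,
    confluence_area,
    detect_spots,
    detect_spots_stack,
    link_tracks,
    surface_morphometry,
    track_speed,
)

from conftest import frame_from

WINDOW = (50.0, 230.0)


def brute_force_cost(a, b, max_dist):
    """Minimum of Σd² + gate·(#unmatched) over all gated partial matchings."""
    gate = max_dist**2
    m, n = len(a), len(b)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    best = np.inf
    for k in range(min(m, n) + 1):
        for rows in itertools.combinations(range(m), k):
            for cols in itertools.permutations(range(n), k):
                if any(d2[r, c] > gate for r, c in zip(rows, cols)):
                    continue
                cost = sum(d2[r, c] for r, c in zip(rows, cols)) + gate * (m - k + n - k)
                best = min(best, cost)
    return best


class TestDetectSpots:
    def test_blank_frame(self):
        assert detect_spots(frame_from(np.zeros((64, 64))), 12, WINDOW) == []

    def test_planted_spots_within_one_pixel(self):
        stack, truth = make_track_movie(n_particles=6, speed=0, n_frames=1, noise_sd=0, seed=3)
        spots = detect_spots(stack[0], 12, WINDOW)
        assert len(spots) == 6
        planted = {
            (r["x_um"], r["y_um"])
            for p in truth.objects["particles"]
            for r in p["trajectory"]
        }
        for x, y, _ in spots:
            assert min(np.hypot(x - px, y - py) for px, py in planted) <= 1.0

    def test_spot_brighter_than_window_excluded(self):
        stack, _ = make_track_movie(
            n_particles=1, speed=0, n_frames=1, noise_sd=0, amplitude=400, seed=0
        )
        assert detect_spots(stack[0], 12, WINDOW) == []

    def test_invalid_window_rejected(self):
        with pytest.raises(ValidationError):
            detect_spots(frame_from(np.zeros((16, 16))), 12, (100, 100))


class TestLinking:
    def test_single_constant_particle_one_track(self):
        stack, _ = make_track_movie(n_particles=1, speed=5, n_frames=10, seed=1)
        spots = detect_spots_stack(stack, 12, WINDOW)
        tracks = link_tracks(spots, max_dist=20, max_gap=5)
        assert len(tracks) == 1
        assert tracks[0].n_detections == 10

    def test_gap_contract(self):
        """A single dropout splits the track iff max_gap = 0."""
        stack, _ = make_track_movie(
            n_particles=1, speed=5, n_frames=10, dropout_frames=[[3]], seed=1
        )
        spots = detect_spots_stack(stack, 12, WINDOW)
        assert len(link_tracks(spots, 20, max_gap=1)) == 1
        assert len(link_tracks(spots, 20, max_gap=0)) == 2

    def test_every_detection_in_at_most_one_track(self):
        stack, _ = make_track_movie(n_particles=5, speed=6, n_frames=15, dropout_rate=0.1, seed=8)
        spots = detect_spots_stack(stack, 12, WINDOW)
        tracks = link_tracks(spots, 20, 5)
        seen = set()
        for tr in tracks:
            for p in tr.points:
                key = (p[0], round(p[1], 6), round(p[2], 6))
                assert key not in seen
                seen.add(key)
        assert len(seen) == sum(len(s) for s in spots)

    @pytest.mark.parametrize("seed", range(5))
    def test_assignment_matches_exhaustive_minimum(self, seed, rng=None):
        """Gated optimal assignment equals brute-force minimum total cost."""
        rng = np.random.default_rng(seed)
        m, n = rng.integers(1, 7), rng.integers(1, 7)
        a = rng.uniform(0, 50, (m, 2))
        b = rng.uniform(0, 50, (n, 2))
        max_dist = 15.0
        links = _gated_assignment(a, b, max_dist)
        gate = max_dist**2
        d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
        cost = sum(d2[r, c] for r, c in links) + gate * (m + n - 2 * len(links))
        assert cost == pytest.approx(brute_force_cost(a, b, max_dist), rel=1e-9)

    def test_crossing_particles_resolved_optimally(self):
        # two trajectories crossing in x while staying in separate y lanes:
        # straight-through linking is strictly cheaper than swapping lanes
        frames = []
        for t in range(9):
            frames.append(
                [(20.0 + 10 * t, 45.0, 100.0), (100.0 - 10 * t, 55.0, 100.0)]
            )
        tracks = link_tracks(frames, max_dist=15, max_gap=0)
        assert len(tracks) == 2
        for tr in tracks:
            ys = {p[2] for p in tr.points}
            assert len(ys) == 1  # each track keeps its lane
            xs = [p[1] for p in tr.points]
            steps = np.diff(xs)
            assert np.all(steps > 0) or np.all(steps < 0)


class TestTrackSpeed:
    def test_constant_speed_closed_form(self):
        tr = Track([(i, 5.0 * i, 0.0) for i in range(6)])
        assert track_speed(tr, frame_interval=20) == pytest.approx(0.25)

    def test_stationary_particle(self):
        tr = Track([(i, 7.0, 7.0) for i in range(4)])
        assert track_speed(tr, 20) == 0.0

    def test_single_detection_undefined(self):
        with pytest.raises(ValidationError):
            track_speed(Track([(0, 1.0, 1.0)]), 20)

    def test_speed_recovered_through_dropout(self):
        stack, truth = make_track_movie(
            n_particles=1, speed=6.0, n_frames=15, dropout_frames=[[4, 9]], seed=5
        )
        spots = detect_spots_stack(stack, 12, WINDOW)
        (track,) = link_tracks(spots, 20, 5)
        vis = [
            (r["frame"], r["x_um"], r["y_um"])
            for r in truth.objects["particles"][0]["trajectory"]
            if r["visible"]
        ]
        planted_speed = track_speed(Track(vis), 20)
        assert track_speed(track, 20) == pytest.approx(planted_speed, rel=0.02)


class TestSurfaceMorphometry:
    @staticmethod
    def ball(radius, pad=5):
        n = 2 * (radius + pad) + 1
        z, y, x = np.mgrid[:n, :n, :n] - (n // 2)
        return x * x + y * y + z * z <= radius**2

    def test_ball_sphericity_near_one(self):
        sm = surface_morphometry(self.ball(20))
        assert 0.95 <= sm.sphericity <= 1.0

    def test_cube_sphericity_closed_form(self):
        cube = np.zeros((30, 30, 30), bool)
        cube[5:25, 5:25, 5:25] = True
        sm = surface_morphometry(cube)
        assert sm.sphericity == pytest.approx((np.pi / 6) ** (1 / 3), abs=0.03)

    def test_volume_exact_voxel_count(self):
        mask = self.ball(10)
        sm = surface_morphometry(mask, voxel_size=(2.0, 2.0, 2.0))
        assert sm.volume == mask.sum() * 8.0

    def test_sphericity_scale_invariant(self):
        psi_small = surface_morphometry(self.ball(10)).sphericity
        psi_big = surface_morphometry(self.ball(20)).sphericity
        assert abs(psi_small - psi_big) <= 0.05

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            surface_morphometry(np.zeros((5, 5, 5), bool))


class TestConfluence:
    def test_blank_frame(self):
        assert confluence_area(frame_from(np.zeros((32, 32)), 2.0), threshold=10) == 0.0

    def test_half_bright_frame(self):
        img = np.zeros((32, 32))
        img[:16] = 100.0
        assert confluence_area(frame_from(img, 2.0), threshold=50) == 16 * 32 * 4.0

    def test_planted_discs_within_perimeter_band(self):
        img = np.zeros((128, 128))
        rr, cc = draw.disk((64, 64), 30)
        img[rr, cc] = 200.0
        area = confluence_area(frame_from(img, 1.5), threshold=100)
        analytic = np.pi * (30 * 1.5) ** 2
        band = 2 * np.pi * 30 * 1.5**2
        assert abs(area - analytic) <= band
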