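"""Spot tracking, 3D surface morphometry, and thresholded-area confluence.

Migration analysis follows the classic two-pass tracker design: per-frame
Laplacian-of-Gaussian spot detection with an intensity filter window, then
globally optimal frame-to-frame linking (assignment problem on squared
displacement with a distance gate), then gap closing that bridges track
ends across up to ``max_gap`` missing frames.  Defaults mirror the
acquisition they were designed for: estimated cell diameter 18 µm,
intensity filter 30–230, max distance jump 20 µm, max gap size 5, frames
every 20 min.

Morphometry reports cell volume, surface area and sphericity
ψ = π^{1/3}(6V)^{2/3}/A from a 3D binary mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import measure
from skimage.feature import peak_local_max

from .errors import ValidationError
from .frames import ImageFrame, ImageStack
from .shapes import sphericity_value

__all__ = [
    "Track",
    "SurfaceMorphometry",
    "detect_spots",
    "detect_spots_stack",
    "link_tracks",
    "track_speed",
    "surface_morphometry",
    "confluence_area",
]

_BIG = 1e12


@dataclass
class Track:
    """One linked trajectory: ordered (frame, x_um, y_um) detections."""

    points: list[tuple[int, float, float]]

    def __post_init__(self) -> None:
        frames = [p[0] for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValidationError("track frame indices must strictly increase")

    @property
    def n_detections(self) -> int:
        return len(self.points)

    @property
    def start_frame(self) -> int:
        return self.points[0][0]

    @property
    def end_frame(self) -> int:
        return self.points[-1][0]


@dataclass
class SurfaceMorphometry:
    """Volume (µm³), surface area (µm²) and sphericity of one object."""

    volume: float
    surface_area: float
    sphericity: float


def detect_spots(
    frame: ImageFrame,
    diameter: float = 18.0,
    intensity_window: tuple[float, float] = (30.0, 230.0),
) -> list[tuple[float, float, float]]:
    """LoG maxima at scale ``diameter/2`` with an intensity filter window.

    Returns ``(x_um, y_um, peak_intensity)`` per spot; peaks closer than
    half a diameter are suppressed (brightest wins).  Sub-pixel positions
    come from a 3-point parabolic fit of the LoG response around each
    maximum.
    """
    lo, hi = intensity_window
    if not lo < hi:
        raise ValidationError("intensity window must satisfy lo < hi")
    px = frame.pixel_size
    if diameter <= 2 * px:
        raise ValidationError("diameter must exceed two pixels")
    pixels = frame.pixels.astype(float)
    radius_px = diameter / 2.0 / px
    sigma_px = radius_px / np.sqrt(2.0)
    resp = -(sigma_px**2) * ndimage.gaussian_laplace(pixels, sigma_px)
    if resp.max() <= 0:
        return []
    peaks = peak_local_max(
        resp,
        min_distance=max(1, int(round(radius_px))),
        threshold_abs=0.05 * float(resp.max()),
    )
    out = []
    h, w = pixels.shape
    for y, x in peaks:
        peak_val = float(pixels[y, x])
        if not lo <= peak_val <= hi:
            continue
        # parabolic sub-pixel refinement on the LoG response
        sy, sx = float(y), float(x)
        if 0 < y < h - 1:
            denom = resp[y - 1, x] - 2 * resp[y, x] + resp[y + 1, x]
            if denom < 0:
                sy += 0.5 * (resp[y - 1, x] - resp[y + 1, x]) / denom
        if 0 < x < w - 1:
            denom = resp[y, x - 1] - 2 * resp[y, x] + resp[y, x + 1]
            if denom < 0:
                sx += 0.5 * (resp[y, x - 1] - resp[y, x + 1]) / denom
        out.append((sx * px, sy * px, peak_val))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def detect_spots_stack(
    stack: ImageStack,
    diameter: float = 18.0,
    intensity_window: tuple[float, float] = (30.0, 230.0),
) -> list[list[tuple[float, float, float]]]:
    """Per-frame spot lists for a time-lapse stack."""
    if stack.axis != "t":
        raise ValidationError('spot tracking expects an axis "t" stack')
    return [detect_spots(f, diameter, intensity_window) for f in stack]


def _gated_assignment(
    a: np.ndarray, b: np.ndarray, max_cost: float
) -> list[tuple[int, int]]:
    """Optimal assignment between point sets with a hard distance gate.

    Standard 4-block construction: the top-left block carries squared
    distances (infeasible pairs get a prohibitive cost), the diagonal
    auxiliary blocks price leaving a point unmatched at the gate cost, so
    the solver only links pairs within the gate.
    """
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        return []
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    gate = max_cost**2
    cost = np.full((m + n, m + n), _BIG)
    tl = np.where(d2 <= gate, d2, _BIG)
    cost[:m, :n] = tl
    cost[m:, n:] = tl.T.copy()
    np.fill_diagonal(cost[:m, n:], gate * 1.0000001)
    np.fill_diagonal(cost[m:, :n], gate * 1.0000001)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if r < m and c < n and d2[r, c] <= gate
    ]


def link_tracks(
    spots: list[list[tuple[float, float, float]]] | list[np.ndarray],
    max_dist: float = 20.0,
    max_gap: int = 5,
) -> list[Track]:
    """Two-pass track linking: optimal frame-to-frame assignment + gap closing.

    ``spots`` is a per-frame list of detections ``(x_um, y_um[, intensity])``.
    Frame-to-frame links minimise total squared displacement among pairs
    within ``max_dist``; unmatched track ends may then be bridged across up
    to ``max_gap`` missing frames when the bridging displacement is at most
    ``max_dist × (gap + 1)``.  Gaps are closed in ascending gap length.
    Every detection belongs to at most one track.
    """
    if max_dist <= 0:
        raise ValidationError("max_dist must be positive")
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    coords = [np.asarray([(s[0], s[1]) for s in fr], float).reshape(-1, 2) for fr in spots]

    tracks: list[list[tuple[int, float, float]]] = []
    open_idx: dict[int, int] = {}  # detection index in current frame -> track idx
    for f in range(len(coords)):
        cur = coords[f]
        new_open: dict[int, int] = {}
        if f > 0 and open_idx:
            prev_ids = sorted(open_idx)
            prev_pts = coords[f - 1][prev_ids]
            for r, c in _gated_assignment(prev_pts, cur, max_dist):
                t = open_idx[prev_ids[r]]
                tracks[t].append((f, float(cur[c, 0]), float(cur[c, 1])))
                new_open[c] = t
        for j in range(len(cur)):
            if j not in new_open:
                tracks.append([(f, float(cur[j, 0]), float(cur[j, 1]))])
                new_open[j] = len(tracks) - 1
        open_idx = new_open

    # gap closing, ascending gap length
    for gap in range(1, max_gap + 1):
        merged = True
        while merged:
            merged = False
            ends = {}
            starts = {}
            for ti, tr in enumerate(tracks):
                if tr is None:
                    continue
                ends.setdefault(tr[-1][0], []).append(ti)
                starts.setdefault(tr[0][0], []).append(ti)
            for fe in sorted(ends):
                fs = fe + gap + 1
                if fs not in starts:
                    continue
                end_tracks = [ti for ti in ends[fe] if tracks[ti] is not None]
                start_tracks = [
                    ti for ti in starts[fs] if tracks[ti] is not None and ti not in end_tracks
                ]
                if not end_tracks or not start_tracks:
                    continue
                a = np.array([tracks[ti][-1][1:] for ti in end_tracks])
                b = np.array([tracks[ti][0][1:] for ti in start_tracks])
                links = _gated_assignment(a, b, max_dist * (gap + 1))
                for r, c in links:
                    ti, tj = end_tracks[r], start_tracks[c]
                    tracks[ti] = tracks[ti] + tracks[tj]
                    tracks[tj] = None
                    merged = True
                if merged:
                    break
    return [Track(tr) for tr in tracks if tr is not None]


def track_speed(track: Track, frame_interval: float = 20.0) -> float:
    """Mean instantaneous speed in µm/min (``frame_interval`` in minutes).

    Averages Euclidean displacement over elapsed time across consecutive
    detections; bridged gaps contribute one displacement over their full
    elapsed time.  A single-detection track has no defined speed.
    """
    if track.n_detections < 2:
        raise ValidationError("speed undefined for a single-detection track")
    if frame_interval <= 0:
        raise ValidationError("frame_interval must be positive")
    speeds = []
    for (f0, x0, y0), (f1, x1, y1) in zip(track.points, track.points[1:]):
        dt = (f1 - f0) * frame_interval
        speeds.append(np.hypot(x1 - x0, y1 - y0) / dt)
    return float(np.mean(speeds))


#: supersampling factor and Gaussian sigma (original-voxel units) used to
#: anti-alias the binary mask before the isosurface is extracted
_SUPERSAMPLE = 3
_MESH_SIGMA = 0.7


def surface_morphometry(
    mask3d: np.ndarray, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> SurfaceMorphometry:
    """Volume, isosurface area and sphericity of a 3D binary mask.

    Volume is the exact voxel count times the voxel volume.  Surface area
    comes from a marching-cubes isosurface at 0.5; the binary mask is first
    ×3 supersampled and lightly Gaussian-smoothed (σ = 0.7 original voxels)
    so staircase facets do not inflate the area of smooth objects, while
    planar faces stay planar.  Voxels are assumed near-isotropic; strongly
    anisotropic data should be resampled first.
    """
    mask3d = np.asarray(mask3d, bool)
    if mask3d.ndim != 3:
        raise ValidationError("mask3d must be a 3D array")
    if not mask3d.any():
        raise ValidationError("empty mask: morphometry undefined")
    vz, vy, vx = voxel_size
    if min(voxel_size) <= 0:
        raise ValidationError("voxel_size components must be positive")
    volume = float(mask3d.sum()) * vz * vy * vx

    f = _SUPERSAMPLE
    up = ndimage.zoom(mask3d.astype(np.float32), f, order=0)
    pad = int(3 * _MESH_SIGMA * f) + 2
    up = np.pad(up, pad)
    up = ndimage.gaussian_filter(up, _MESH_SIGMA * f)
    verts, faces, _, _ = measure.marching_cubes(
        up, 0.5, spacing=(vz / f, vy / f, vx / f)
    )
    area = float(measure.mesh_surface_area(verts, faces))
    return SurfaceMorphometry(
        volume=volume,
        surface_area=area,
        sphericity=sphericity_value(volume, area),
    )


def confluence_area(
    frame: ImageFrame, threshold: float, pixel_size: float | None = None
) -> float:
    """Occupied area (µm²): pixels above a high intensity threshold."""
    px = pixel_size if pixel_size is not None else frame.pixel_size
    return float((frame.pixels.astype(float) > threshold).sum() * px**2)
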