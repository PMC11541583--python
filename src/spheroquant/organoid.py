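"""Organoid-field live/dead cytometry.

Fields of many small round spheroids are imaged in two 16-bit channels:
green (calcein, live cells) and orange (ethidium, dead cells).  Dead cells
are detected by merging two engines — a dot-like structure detector
(Laplacian-of-Gaussian blobs with a centre-drop check: bright centre,
radially decreasing intensity) and an intensity-threshold detector — while
live cells use the threshold engine alone.  Spheroids themselves are
detected by a double threshold on intensity and area, and per-spheroid
statistics (area, circularity, live/dead counts and mean intensities) are
assembled from the detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.feature import peak_local_max

from .errors import ValidationError
from .frames import ImageFrame, ImageStack
from .shapes import circularity

__all__ = [
    "DotDetection",
    "SpheroidRecord",
    "detect_dead_cells",
    "detect_live_cells",
    "detect_spheroids",
    "spheroid_stats",
    "max_projection",
]


@dataclass
class DotDetection:
    """Detected puncta: positions (µm), peak intensities, and footprint mask."""

    points: np.ndarray  # (N, 2) of (x_um, y_um)
    intensities: np.ndarray  # (N,)
    mask: np.ndarray  # bool footprint of all detections
    engine1_mask: np.ndarray | None = None  # dot-like structure engine
    engine2_mask: np.ndarray | None = None  # intensity-threshold engine

    @property
    def count(self) -> int:
        return len(self.points)


@dataclass
class SpheroidRecord:
    """Per-spheroid cytometry read-out (area µm², intensities native units)."""

    spheroid_id: int
    area: float
    circularity: float
    live_count: int
    dead_count: int
    live_mean_int: float
    dead_mean_int: float


def _resolve_threshold(pixels: np.ndarray, thresh: float, relative: bool) -> float:
    """A fractional threshold is taken relative to the image maximum."""
    if relative:
        if not 0 < thresh <= 1:
            raise ValidationError("relative intensity_thresh must lie in (0, 1]")
        return float(thresh * pixels.max()) if pixels.size else 0.0
    return float(thresh)


def _log_response(pixels: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalised negative LoG: positive at bright blobs."""
    return -(sigma_px**2) * ndimage.gaussian_laplace(pixels.astype(float), sigma_px)


def _ring_mean(pixels: np.ndarray, y: int, x: int, radius_px: float) -> float:
    """Mean intensity on a one-pixel-wide ring at the given radius."""
    h, w = pixels.shape
    n = max(8, int(2 * np.pi * radius_px))
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ys = np.clip(np.rint(y + radius_px * np.sin(angles)).astype(int), 0, h - 1)
    xs = np.clip(np.rint(x + radius_px * np.cos(angles)).astype(int), 0, w - 1)
    return float(pixels[ys, xs].mean())


def _enforce_separation(
    peaks: np.ndarray, intensities: np.ndarray, min_sep_px: float
) -> np.ndarray:
    """Greedy suppression: keep brighter peaks, deterministic tie order."""
    if len(peaks) == 0:
        return np.zeros(0, dtype=int)
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -intensities))
    kept: list[int] = []
    for idx in order:
        p = peaks[idx]
        if all(np.hypot(*(p - peaks[j])) >= min_sep_px for j in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=int)


def _min_dot_area_px(cell_diameter: float, pixel_size: float, min_dot_area: float | None) -> float:
    """Area floor (px) for a threshold component to count as one cell.

    Defaults to a disc of half the cell diameter — smaller islands are
    noise specks, not stained cells.
    """
    if min_dot_area is None:
        min_dot_area = np.pi * (cell_diameter / 4.0) ** 2
    return min_dot_area / pixel_size**2


def detect_dead_cells(
    dead_channel: ImageFrame,
    cell_diameter: float = 12.0,
    intensity_thresh: float = 0.5,
    centre_drop: float = 0.3,
    relative: bool = True,
    min_dot_area: float | None = None,
) -> DotDetection:
    """Dual-engine dead-cell detection with mask merging.

    Engine 1 finds dot-like structures: maxima of the Laplacian-of-Gaussian
    response at scale ``cell_diameter/2`` whose intensity falls by at least
    ``centre_drop`` (fraction of the peak-above-background) within one
    radius.  Engine 2 is a plain intensity-threshold mask whose components
    must also clear ``min_dot_area`` (µm²; default a disc of half the cell
    diameter) before contributing a point.  The final mask is the union of
    both engines' masks; the final points are the engine-1 maxima plus
    centroids of surviving engine-2 components not already claimed by an
    engine-1 point.  The returned detection keeps both engine masks for
    inspection.
    """
    px = dead_channel.pixel_size
    if cell_diameter <= 2 * px:
        raise ValidationError("cell_diameter must exceed two pixels")
    pixels = dead_channel.pixels.astype(float)
    radius_px = cell_diameter / 2.0 / px
    sigma_px = radius_px / np.sqrt(2.0)
    thr = _resolve_threshold(pixels, intensity_thresh, relative)

    # engine 1: dot-like structures
    resp = _log_response(pixels, sigma_px)
    if resp.max() > 0:
        cand = peak_local_max(
            resp,
            min_distance=max(1, int(round(radius_px))),
            threshold_abs=0.05 * float(resp.max()),
        )
    else:
        cand = np.zeros((0, 2), int)
    floor = float(np.median(pixels))
    # robust noise scale; a genuine dot must rise well above the noise
    noise_sigma = 1.4826 * float(np.median(np.abs(pixels - floor)))
    min_amplitude = 5.0 * noise_sigma
    peaks = []
    peak_int = []
    for y, x in cand:
        centre = float(pixels[y, x])
        ring = _ring_mean(pixels, y, x, radius_px)
        amplitude = centre - floor
        if amplitude <= min_amplitude or amplitude <= 0:
            continue
        if (centre - ring) / amplitude >= centre_drop:
            peaks.append((y, x))
            peak_int.append(centre)
    peaks = np.asarray(peaks, float).reshape(-1, 2)
    peak_int = np.asarray(peak_int, float)
    keep = _enforce_separation(peaks, peak_int, radius_px)
    peaks, peak_int = peaks[keep], peak_int[keep]

    engine1_mask = np.zeros(pixels.shape, bool)
    disk = morphology.disk(max(1, int(round(radius_px)))).astype(bool)
    for y, x in peaks.astype(int):
        y0, x0 = y - disk.shape[0] // 2, x - disk.shape[1] // 2
        ys = slice(max(0, y0), min(pixels.shape[0], y0 + disk.shape[0]))
        xs = slice(max(0, x0), min(pixels.shape[1], x0 + disk.shape[1]))
        dys = slice(ys.start - y0, ys.stop - y0)
        dxs = slice(xs.start - x0, xs.stop - x0)
        engine1_mask[ys, xs] |= disk[dys, dxs]

    # engine 2: intensity threshold
    engine2_mask = pixels > thr

    final_mask = engine1_mask | engine2_mask
    min_px = _min_dot_area_px(cell_diameter, px, min_dot_area)
    points = [(x * px, y * px) for y, x in peaks]
    intensities = list(peak_int)
    labels = measure.label(engine2_mask, connectivity=2)
    for region in measure.regionprops(labels, intensity_image=pixels):
        if region.area < min_px:
            continue
        cy, cx = region.centroid
        claimed = any(
            np.hypot(cx - p[0] / px, cy - p[1] / px) < 2 * radius_px for p in points
        )
        if not claimed:
            points.append((cx * px, cy * px))
            intensities.append(float(region.intensity_max))
    pts = np.asarray(points, float).reshape(-1, 2)
    return DotDetection(
        pts,
        np.asarray(intensities, float),
        final_mask,
        engine1_mask=engine1_mask,
        engine2_mask=engine2_mask,
    )


def detect_live_cells(
    live_channel: ImageFrame,
    cell_diameter: float = 12.0,
    intensity_thresh: float = 0.5,
    relative: bool = True,
    min_dot_area: float | None = None,
) -> DotDetection:
    """Single-engine live-cell detection: threshold mask + component centroids.

    Components below ``min_dot_area`` (µm²; same default as the dead-cell
    engine) are treated as noise specks and yield no point.
    """
    px = live_channel.pixel_size
    if cell_diameter <= 2 * px:
        raise ValidationError("cell_diameter must exceed two pixels")
    pixels = live_channel.pixels.astype(float)
    thr = _resolve_threshold(pixels, intensity_thresh, relative)
    mask = pixels > thr
    min_px = _min_dot_area_px(cell_diameter, px, min_dot_area)
    labels = measure.label(mask, connectivity=2)
    points = []
    intensities = []
    for region in measure.regionprops(labels, intensity_image=pixels):
        if region.area < min_px:
            continue
        cy, cx = region.centroid
        points.append((cx * px, cy * px))
        intensities.append(float(region.intensity_max))
    pts = np.asarray(points, float).reshape(-1, 2)
    return DotDetection(pts, np.asarray(intensities, float), mask)


def detect_spheroids(
    live_channel: ImageFrame,
    intensity_thresh: float = 0.25,
    min_area: float = 1000.0,
    max_area: float | None = None,
    relative: bool = True,
) -> np.ndarray:
    """Double-threshold spheroid detection: intensity AND area.

    Threshold → hole-fill → connected components → discard components whose
    area (µm²) falls below ``min_area`` (or above ``max_area`` if given).
    Survivors are relabelled 1..K in scan order.  A fractional
    ``intensity_thresh`` (relative) makes the detection invariant to global
    intensity rescaling.
    """
    if min_area < 0:
        raise ValidationError("min_area must be >= 0")
    pixels = live_channel.pixels.astype(float)
    thr = _resolve_threshold(pixels, intensity_thresh, relative)
    mask = ndimage.binary_fill_holes(pixels > thr)
    labels = measure.label(mask, connectivity=2)
    px2 = live_channel.pixel_size**2
    out = np.zeros_like(labels)
    next_id = 1
    for lab in range(1, labels.max() + 1):
        component = labels == lab
        area = component.sum() * px2
        if area < min_area:
            continue
        if max_area is not None and area > max_area:
            continue
        out[component] = next_id
        next_id += 1
    return out


def _points_in_label(points: np.ndarray, labels: np.ndarray, px: float, lab: int) -> np.ndarray:
    """Boolean selector for points whose pixel lies in the given label.

    A point on a boundary pixel of the spheroid counts as inside.
    """
    if len(points) == 0:
        return np.zeros(0, bool)
    cols = np.clip(np.rint(points[:, 0] / px).astype(int), 0, labels.shape[1] - 1)
    rows = np.clip(np.rint(points[:, 1] / px).astype(int), 0, labels.shape[0] - 1)
    return labels[rows, cols] == lab


def spheroid_stats(
    spheroids: np.ndarray,
    live: DotDetection,
    dead: DotDetection,
    live_channel: ImageFrame,
    dead_channel: ImageFrame,
    pixel_size: float,
) -> tuple[list[SpheroidRecord], dict]:
    """Per-spheroid area, circularity, live/dead counts and mean intensities.

    Mean intensities are taken over the member dot footprints inside the
    spheroid (NaN when a spheroid holds no dots of that kind).  The summary
    carries the total event count (spheroid number).
    """
    if spheroids.shape != live_channel.shape or spheroids.shape != dead_channel.shape:
        raise ValidationError("label mask and channels must share geometry")
    records = []
    k = int(spheroids.max())
    live_px = live_channel.pixels.astype(float)
    dead_px = dead_channel.pixels.astype(float)
    px2 = pixel_size**2
    for lab in range(1, k + 1):
        footprint = spheroids == lab
        live_sel = _points_in_label(live.points, spheroids, pixel_size, lab)
        dead_sel = _points_in_label(dead.points, spheroids, pixel_size, lab)
        live_foot = live.mask & footprint
        dead_foot = dead.mask & footprint
        records.append(
            SpheroidRecord(
                spheroid_id=lab,
                area=float(footprint.sum() * px2),
                circularity=circularity(ndimage.binary_fill_holes(footprint)),
                live_count=int(live_sel.sum()),
                dead_count=int(dead_sel.sum()),
                live_mean_int=float(live_px[live_foot].mean()) if live_foot.any() else float("nan"),
                dead_mean_int=float(dead_px[dead_foot].mean()) if dead_foot.any() else float("nan"),
            )
        )
    return records, {"spheroid_count": k}


def max_projection(stack: ImageStack) -> ImageFrame:
    """Per-pixel maximum intensity projection of a z-stack."""
    if stack.axis != "z":
        raise ValidationError('max_projection expects an axis "z" stack')
    arr = stack.as_array()
    return stack.frames[0].with_pixels(arr.max(axis=0))
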