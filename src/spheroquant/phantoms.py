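"""Ground-truthed synthetic microscopy phantoms.

Each generator renders one of the four assay geometries the analysis
pipelines target and returns the image(s) together with a
:class:`PhantomTruth` recording exactly what was planted — the test oracle
for every downstream stage:

* :func:`make_stellate` — one dense circular spheroid core with radiating
  strands of invading cells on an uneven-illumination background
  (brightfield stellate-spheroid invasion assay, rendered bright-on-dark).
* :func:`make_organoid_field` — a two-channel field of many small round
  spheroids carrying bright punctate live (green) and dead (orange) cells.
* :func:`make_tube_lattice` — a honeycomb-like endothelial tube network
  with known junction, segment and mesh counts.
* :func:`make_track_movie` — moving bright spots with known speeds and
  scheduled missed detections.

Noise follows the standard fluorescence imaging model: Poisson shot noise
on the signal plus additive Gaussian read noise, both optional.  Uneven
illumination is a multiplicative planar field.  All randomness flows from
one integer seed; identical seeds give byte-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
from skimage import draw, morphology

from .errors import PackingError, ValidationError
from .frames import ImageFrame, ImageStack

__all__ = [
    "PhantomTruth",
    "make_stellate",
    "make_organoid_field",
    "make_tube_lattice",
    "make_track_movie",
]


@dataclass
class PhantomTruth:
    """Planted-object ground truth for one phantom image.

    ``objects`` holds kind-specific records (masks as boolean arrays under
    keys ending in ``_mask``; geometry and scalar truths as plain types).
    :meth:`to_json` serialises everything except the raw mask arrays.
    """

    kind: str
    objects: dict[str, Any]
    params: dict[str, Any]
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        def _clean(value):
            if isinstance(value, np.ndarray):
                if value.dtype == bool:
                    return {"__mask_area_px__": int(value.sum())}
                return value.tolist()
            if isinstance(value, dict):
                return {k: _clean(v) for k, v in value.items()}
            if isinstance(value, (list, tuple)):
                return [_clean(v) for v in value]
            if isinstance(value, (np.integer,)):
                return int(value)
            if isinstance(value, (np.floating,)):
                return float(value)
            return value

        payload = json.dumps(
            {
                "kind": self.kind,
                "seed": self.seed,
                "params": _clean(self.params),
                "objects": _clean(self.objects),
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload


def _quantize(img: np.ndarray, bit_depth: int = 16) -> np.ndarray:
    hi = 2**bit_depth - 1
    return np.clip(np.rint(img), 0, hi).astype(np.uint16 if bit_depth == 16 else np.uint8)


def _apply_noise(
    img: np.ndarray, rng: np.random.Generator, poisson: bool, noise_sd: float
) -> np.ndarray:
    out = img.astype(float)
    if poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return out


def _illumination_field(shape: tuple[int, int], gradient: float) -> np.ndarray:
    """Multiplicative planar field spanning 1−g/2 … 1+g/2 left to right."""
    h, w = shape
    ramp = np.linspace(-0.5, 0.5, w)
    return 1.0 + gradient * np.tile(ramp, (h, 1))


# ---------------------------------------------------------------------------
# stellate spheroid
# ---------------------------------------------------------------------------


def make_stellate(
    core_radius: float = 150.0,
    n_strands: int = 12,
    strand_length: float = 200.0,
    cell_density: float = 0.04,
    seed: int = 0,
    *,
    cell_radius: float = 10.0,
    strand_gap: float = 20.0,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 2.0,
    background: float = 100.0,
    core_intensity: float = 800.0,
    cell_intensity: float = 600.0,
    illum_gradient: float = 0.2,
    noise_sd: float = 20.0,
    poisson: bool = True,
    angle_jitter: float = 0.15,
) -> tuple[ImageFrame, PhantomTruth]:
    """Render a single stellate spheroid: dense core + radial invader strands.

    Parameters are in physical units: ``core_radius``, ``strand_length``,
    ``cell_radius`` and ``strand_gap`` in µm, ``cell_density`` in cells/µm of
    strand.  Strand cells are hard discs starting ``strand_gap`` beyond the
    core rim so core and invader truth masks are disjoint.  The truth records
    the rasterised core and invader masks and their exact planted areas.
    """
    if core_radius <= 0:
        raise ValidationError("core_radius must be positive")
    if n_strands < 0:
        raise ValidationError("n_strands must be >= 0")
    h, w = image_shape
    half_extent = min(h, w) / 2.0 * pixel_size
    reach = core_radius + (strand_gap + strand_length + cell_radius if n_strands else 0.0)
    if reach >= half_extent:
        raise ValidationError(
            f"geometry (reach {reach:.0f} µm) exceeds image half-extent "
            f"({half_extent:.0f} µm)"
        )
    rng = np.random.default_rng(seed)
    cy, cx = h / 2.0, w / 2.0

    core_mask = np.zeros((h, w), bool)
    rr, cc = draw.disk((cy, cx), core_radius / pixel_size, shape=(h, w))
    core_mask[rr, cc] = True

    invader_mask = np.zeros((h, w), bool)
    strands: list[dict[str, Any]] = []
    spacing = 1.0 / cell_density if cell_density > 0 else np.inf
    base_angles = np.linspace(0, 2 * np.pi, n_strands, endpoint=False)
    for ang0 in base_angles:
        ang = ang0 + rng.uniform(-angle_jitter, angle_jitter)
        cells = []
        r = core_radius + strand_gap + cell_radius
        while r <= core_radius + strand_gap + strand_length:
            x_um = cx * pixel_size + r * np.cos(ang)
            y_um = cy * pixel_size + r * np.sin(ang)
            rr, cc = draw.disk(
                (y_um / pixel_size, x_um / pixel_size),
                cell_radius / pixel_size,
                shape=(h, w),
            )
            invader_mask[rr, cc] = True
            cells.append((float(x_um), float(y_um)))
            r += spacing
        strands.append({"angle_rad": float(ang), "cells_xy_um": cells})

    signal = np.full((h, w), background, float)
    signal[core_mask] = core_intensity
    signal[invader_mask & ~core_mask] = cell_intensity
    signal *= _illumination_field((h, w), illum_gradient)
    noisy = _apply_noise(signal, rng, poisson, noise_sd)
    frame = ImageFrame(_quantize(noisy), bit_depth=16, pixel_size=pixel_size, channel="grey")

    px_area = pixel_size**2
    truth = PhantomTruth(
        kind="stellate",
        objects={
            "core_mask": core_mask,
            "invader_mask": invader_mask,
            "core_area_um2": float(core_mask.sum() * px_area),
            "invader_area_um2": float((invader_mask & ~core_mask).sum() * px_area),
            "core_center_xy_um": (float(cx * pixel_size), float(cy * pixel_size)),
            "strands": strands,
        },
        params=dict(
            core_radius=core_radius,
            n_strands=n_strands,
            strand_length=strand_length,
            cell_density=cell_density,
            cell_radius=cell_radius,
            strand_gap=strand_gap,
            image_shape=list(image_shape),
            pixel_size=pixel_size,
            background=background,
            core_intensity=core_intensity,
            cell_intensity=cell_intensity,
            illum_gradient=illum_gradient,
            noise_sd=noise_sd,
            poisson=poisson,
        ),
        seed=seed,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# organoid field (two channels)
# ---------------------------------------------------------------------------


def _gaussian_dot(
    img: np.ndarray, y: float, x: float, sigma_px: float, amplitude: float
) -> None:
    """Add an isotropic Gaussian dot (bright centre, radially decaying)."""
    h, w = img.shape
    r = int(np.ceil(4 * sigma_px))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma_px**2)
    )


def _place_points(
    rng: np.random.Generator,
    n: int,
    center: tuple[float, float],
    max_r: float,
    min_sep: float,
    retries: int = 200,
) -> list[tuple[float, float]]:
    """Rejection-sample up to n points in a disc with pairwise separation."""
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        for _ in range(retries):
            rad = max_r * np.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * np.pi)
            p = (center[0] + rad * np.cos(th), center[1] + rad * np.sin(th))
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_sep for q in pts):
                pts.append(p)
                break
        # silently keep fewer points if the disc cannot hold n at min_sep;
        # the truth records what was actually planted
    return pts


def make_organoid_field(
    n_spheroids: int = 12,
    radius_range: tuple[float, float] = (30.0, 60.0),
    live_per_spheroid: tuple[int, int] = (2, 6),
    dead_per_spheroid: tuple[int, int] = (1, 4),
    min_separation: float = 20.0,
    seed: int = 0,
    *,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size: float = 1.6,
    background: float = 100.0,
    disc_intensity: float = 400.0,
    puncta_amplitude: float = 800.0,
    puncta_diameter: float = 12.0,
    noise_sd: float = 20.0,
    poisson: bool = True,
    max_attempts: int = 5000,
) -> tuple[tuple[ImageFrame, ImageFrame], PhantomTruth]:
    """Render a live/dead two-channel organoid field.

    The green channel carries spheroid discs plus live-cell puncta; the
    orange channel carries dead-cell puncta.  Puncta are isotropic Gaussians
    (σ = diameter/4: bright centre, radially decreasing), separated by at
    least two diameters within a spheroid.  The truth lists per-spheroid
    disc geometry and the exact live/dead point lists.

    Returns ``((green_frame, orange_frame), truth)``.
    """
    h, w = image_shape
    if radius_range[0] > radius_range[1] or radius_range[0] <= 0:
        raise ValidationError("radius_range must be (lo, hi) with 0 < lo <= hi")
    rng = np.random.default_rng(seed)
    margin = radius_range[1] / pixel_size + 2

    centers: list[tuple[float, float]] = []  # (y_px, x_px)
    radii: list[float] = []  # µm
    attempts = 0
    while len(centers) < n_spheroids:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed only {len(centers)}/{n_spheroids} spheroids after "
                f"{max_attempts} attempts (min_separation={min_separation} µm)"
            )
        attempts += 1
        r_um = rng.uniform(*radius_range)
        y = rng.uniform(margin, h - margin)
        x = rng.uniform(margin, w - margin)
        ok = True
        for (yq, xq), rq in zip(centers, radii):
            d_um = np.hypot(y - yq, x - xq) * pixel_size
            if d_um < r_um + rq + min_separation:
                ok = False
                break
        if ok:
            centers.append((y, x))
            radii.append(r_um)

    green = np.full((h, w), background, float)
    orange = np.full((h, w), background, float)
    sigma_px = (puncta_diameter / 4.0) / pixel_size
    spheroids: list[dict[str, Any]] = []
    for sid, ((y, x), r_um) in enumerate(zip(centers, radii), start=1):
        rr, cc = draw.disk((y, x), r_um / pixel_size, shape=(h, w))
        green[rr, cc] = background + disc_intensity
        disc_area = float(len(rr) * pixel_size**2)
        n_live = int(rng.integers(live_per_spheroid[0], live_per_spheroid[1] + 1))
        n_dead = int(rng.integers(dead_per_spheroid[0], dead_per_spheroid[1] + 1))
        center_um = (x * pixel_size, y * pixel_size)
        inner_r = max(r_um - puncta_diameter, puncta_diameter / 2)
        live_pts = _place_points(rng, n_live, center_um, inner_r, 2 * puncta_diameter)
        dead_pts = _place_points(rng, n_dead, center_um, inner_r, 2 * puncta_diameter)
        for (x_um, y_um) in live_pts:
            _gaussian_dot(green, y_um / pixel_size, x_um / pixel_size, sigma_px, puncta_amplitude)
        for (x_um, y_um) in dead_pts:
            _gaussian_dot(orange, y_um / pixel_size, x_um / pixel_size, sigma_px, puncta_amplitude)
        spheroids.append(
            {
                "spheroid_id": sid,
                "center_xy_um": (float(center_um[0]), float(center_um[1])),
                "radius_um": float(r_um),
                "disc_area_um2": disc_area,
                "live_xy_um": [(float(a), float(b)) for a, b in live_pts],
                "dead_xy_um": [(float(a), float(b)) for a, b in dead_pts],
            }
        )

    green_n = _apply_noise(green, rng, poisson, noise_sd)
    orange_n = _apply_noise(orange, rng, poisson, noise_sd)
    green_f = ImageFrame(_quantize(green_n), 16, pixel_size, channel="calcein")
    orange_f = ImageFrame(_quantize(orange_n), 16, pixel_size, channel="ethidium")

    truth = PhantomTruth(
        kind="organoid",
        objects={
            "spheroids": spheroids,
            "n_spheroids": len(spheroids),
            "total_live": int(sum(len(s["live_xy_um"]) for s in spheroids)),
            "total_dead": int(sum(len(s["dead_xy_um"]) for s in spheroids)),
        },
        params=dict(
            n_spheroids=n_spheroids,
            radius_range=list(radius_range),
            live_per_spheroid=list(live_per_spheroid),
            dead_per_spheroid=list(dead_per_spheroid),
            min_separation=min_separation,
            image_shape=list(image_shape),
            pixel_size=pixel_size,
            background=background,
            disc_intensity=disc_intensity,
            puncta_amplitude=puncta_amplitude,
            puncta_diameter=puncta_diameter,
            noise_sd=noise_sd,
            poisson=poisson,
        ),
        seed=seed,
    )
    return (green_f, orange_f), truth


# ---------------------------------------------------------------------------
# tube lattice
# ---------------------------------------------------------------------------


def make_tube_lattice(
    rows: int = 3,
    cols: int = 3,
    edge_len: float = 100.0,
    tube_width: float = 12.0,
    jitter: float = 0.0,
    seed: int = 0,
    *,
    pixel_size: float = 2.0,
    margin: float = 40.0,
    background: float = 100.0,
    tube_intensity: float = 600.0,
    noise_sd: float = 10.0,
    poisson: bool = True,
) -> tuple[ImageFrame, PhantomTruth]:
    """Render a (rows × cols)-mesh rectangular lattice of bright tubes.

    The truth stores the generating graph: node positions and degrees, edge
    list with Euclidean lengths, face count ``rows*cols`` and per-face open
    areas.  For ``jitter=0`` the open area of each face is exactly
    ``(edge_len − tube_width)²``; jittered faces store the centreline
    shoelace area with the same first-order tube-width correction.
    """
    if rows < 1 or cols < 1:
        raise ValidationError("rows and cols must be >= 1")
    if tube_width >= edge_len:
        raise ValidationError("tube_width must be smaller than edge_len (tubes merge)")
    rng = np.random.default_rng(seed)

    ny, nx = rows + 1, cols + 1
    # node positions in µm, row-major index i*nx + j
    pos = np.zeros((ny, nx, 2))  # (y, x)
    for i in range(ny):
        for j in range(nx):
            pos[i, j] = (margin + i * edge_len, margin + j * edge_len)
    if jitter > 0:
        pos += rng.uniform(-jitter, jitter, size=pos.shape)

    height_um = margin * 2 + rows * edge_len
    width_um = margin * 2 + cols * edge_len
    h = int(np.ceil(height_um / pixel_size))
    w = int(np.ceil(width_um / pixel_size))

    edges: list[tuple[int, int]] = []
    for i in range(ny):
        for j in range(nx):
            if j + 1 < nx:
                edges.append((i * nx + j, i * nx + j + 1))
            if i + 1 < ny:
                edges.append((i * nx + j, (i + 1) * nx + j))
    flat_pos = pos.reshape(-1, 2)

    centerline = np.zeros((h, w), bool)
    edge_lengths = []
    for a, b in edges:
        (ya, xa), (yb, xb) = flat_pos[a], flat_pos[b]
        edge_lengths.append(float(np.hypot(yb - ya, xb - xa)))
        rr, cc = draw.line(
            int(round(ya / pixel_size)),
            int(round(xa / pixel_size)),
            int(round(yb / pixel_size)),
            int(round(xb / pixel_size)),
        )
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        centerline[rr[keep], cc[keep]] = True
    half_w_px = max(1, int(round(tube_width / 2.0 / pixel_size)))
    tube_mask = morphology.dilation(centerline, morphology.disk(half_w_px))
    # rasterised tube width: dilation adds half_w_px each side of the 1-px centreline
    eff_width = (2 * half_w_px + 1) * pixel_size

    degrees = np.full((ny, nx), 4, int)
    degrees[0, :] -= 1
    degrees[-1, :] -= 1
    degrees[:, 0] -= 1
    degrees[:, -1] -= 1

    faces = []
    for i in range(rows):
        for j in range(cols):
            quad = [pos[i, j], pos[i, j + 1], pos[i + 1, j + 1], pos[i + 1, j]]
            ys = [p[0] for p in quad]
            xs = [p[1] for p in quad]
            area = 0.5 * abs(
                sum(
                    xs[k] * ys[(k + 1) % 4] - xs[(k + 1) % 4] * ys[k]
                    for k in range(4)
                )
            )
            per = sum(
                np.hypot(
                    ys[(k + 1) % 4] - ys[k], xs[(k + 1) % 4] - xs[k]
                )
                for k in range(4)
            )
            open_area = area - eff_width / 2.0 * per + eff_width**2
            faces.append(
                {"centerline_area_um2": float(area), "open_area_um2": float(open_area)}
            )

    signal = np.full((h, w), background, float)
    signal[tube_mask] = background + tube_intensity
    noisy = _apply_noise(signal, rng, poisson, noise_sd)
    frame = ImageFrame(_quantize(noisy), 16, pixel_size, channel="grey")

    truth = PhantomTruth(
        kind="tubes",
        objects={
            "tube_mask": tube_mask,
            "node_xy_um": [(float(x), float(y)) for y, x in flat_pos],
            "node_degrees": degrees.reshape(-1).tolist(),
            "n_junctions": int((degrees >= 3).sum()),
            "edges": [(int(a), int(b)) for a, b in edges],
            "edge_lengths_um": edge_lengths,
            "total_edge_len_um": float(sum(edge_lengths)),
            "n_meshes": rows * cols,
            "faces": faces,
            "total_open_area_um2": float(sum(f["open_area_um2"] for f in faces)),
        },
        params=dict(
            rows=rows,
            cols=cols,
            edge_len=edge_len,
            tube_width=tube_width,
            jitter=jitter,
            pixel_size=pixel_size,
            margin=margin,
            background=background,
            tube_intensity=tube_intensity,
            noise_sd=noise_sd,
            poisson=poisson,
        ),
        seed=seed,
    )
    return frame, truth


# ---------------------------------------------------------------------------
# track movie
# ---------------------------------------------------------------------------


def make_track_movie(
    n_particles: int = 6,
    speed: float = 5.0,
    n_frames: int = 20,
    dropout_frames: Sequence[Sequence[int]] | None = None,
    max_jitter: float = 0.0,
    seed: int = 0,
    *,
    dropout_rate: float = 0.0,
    image_shape: tuple[int, int] = (256, 256),
    pixel_size: float = 1.0,
    frame_interval: float = 20.0,
    spot_sigma: float = 3.0,
    amplitude: float = 150.0,
    background: float = 20.0,
    noise_sd: float = 3.0,
    poisson: bool = False,
    min_start_separation: float = 30.0,
) -> tuple[ImageStack, PhantomTruth]:
    """Render a time-lapse of Gaussian spots moving at constant speed.

    Each particle starts at a random position (pairwise separated by
    ``min_start_separation`` µm), moves ``speed`` µm/frame in a random
    direction, reflecting at the field margins, with optional per-frame
    positional jitter (uniform in a disc of radius ``max_jitter``).  Missed
    detections come either from an explicit per-particle ``dropout_frames``
    list or independently at ``dropout_rate`` on interior frames.  The truth
    holds exact per-frame positions and visibility flags.
    """
    if n_particles < 0 or n_frames < 1:
        raise ValidationError("need n_particles >= 0 and n_frames >= 1")
    h, w = image_shape
    rng = np.random.default_rng(seed)
    margin_um = 4 * spot_sigma + 2
    lo_y, hi_y = margin_um, h * pixel_size - margin_um
    lo_x, hi_x = margin_um, w * pixel_size - margin_um

    starts: list[tuple[float, float]] = []
    for _ in range(n_particles):
        for _ in range(2000):
            p = (rng.uniform(lo_x, hi_x), rng.uniform(lo_y, hi_y))
            if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_start_separation for q in starts):
                starts.append(p)
                break
        else:
            raise PackingError("could not place particles at min_start_separation")

    if dropout_frames is not None and len(dropout_frames) != n_particles:
        raise ValidationError("dropout_frames must have one list per particle")

    particles = []
    for pid in range(n_particles):
        theta = rng.uniform(0, 2 * np.pi)
        vx, vy = speed * np.cos(theta), speed * np.sin(theta)
        x, y = starts[pid]
        if dropout_frames is not None:
            dropped = set(int(f) for f in dropout_frames[pid])
        else:
            dropped = {
                f
                for f in range(1, n_frames - 1)
                if dropout_rate > 0 and rng.uniform() < dropout_rate
            }
        traj = []
        for f in range(n_frames):
            jx = jy = 0.0
            if max_jitter > 0:
                jr = max_jitter * np.sqrt(rng.uniform())
                jt = rng.uniform(0, 2 * np.pi)
                jx, jy = jr * np.cos(jt), jr * np.sin(jt)
            traj.append(
                {
                    "frame": f,
                    "x_um": float(x + jx),
                    "y_um": float(y + jy),
                    "visible": f not in dropped,
                }
            )
            x, y = x + vx, y + vy
            if x < lo_x or x > hi_x:
                vx = -vx
                x = float(np.clip(x, lo_x, hi_x))
            if y < lo_y or y > hi_y:
                vy = -vy
                y = float(np.clip(y, lo_y, hi_y))
        particles.append({"particle_id": pid, "trajectory": traj})

    sigma_px = spot_sigma / pixel_size
    frames = []
    for f in range(n_frames):
        img = np.full((h, w), background, float)
        for p in particles:
            rec = p["trajectory"][f]
            if rec["visible"]:
                _gaussian_dot(
                    img, rec["y_um"] / pixel_size, rec["x_um"] / pixel_size, sigma_px, amplitude
                )
        noisy = _apply_noise(img, rng, poisson, noise_sd)
        frames.append(ImageFrame(_quantize(noisy), 16, pixel_size, channel="mKO2"))
    stack = ImageStack(frames, axis="t", spacing=frame_interval * 60.0)

    truth = PhantomTruth(
        kind="tracks",
        objects={"particles": particles, "n_particles": n_particles},
        params=dict(
            n_particles=n_particles,
            speed=speed,
            n_frames=n_frames,
            max_jitter=max_jitter,
            dropout_rate=dropout_rate,
            image_shape=list(image_shape),
            pixel_size=pixel_size,
            frame_interval=frame_interval,
            spot_sigma=spot_sigma,
            amplitude=amplitude,
            background=background,
            noise_sd=noise_sd,
            poisson=poisson,
        ),
        seed=seed,
    )
    return stack, truth
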