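"""View construction and maximum-intensity projection of the subchondral plate.

Two orthographic views cover the curved trochlear-ridge surface: a proximal
view looking along the proximodistal axis, and a "distal" view obtained by
tilting the proximal view by ~90 degrees about the mediolateral axis.  For
each image pixel a parallel ray is cast along the line of sight; the first
intersection with the bone mask marks the outer joint surface, and the pixel
value is the maximum HU over a fixed depth window beyond that point
(default 1.5 mm, the nominal subchondral-plate thickness), restricted to
masked positions.  The plate is thus realised as the depth-limited ray
window rather than a separate 3-D plate mask.

Pixel grids tightly bound the projected mask silhouette plus a one-pixel
margin, so image extents are deterministic functions of the mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from .segmentation import BoneMask
from .volume_io import CtVolume

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class ViewSpec:
    """An orthographic view: line of sight plus in-plane image basis.

    ``line_of_sight`` points from the viewer *into* the volume.  ``u`` spans
    image columns (x), ``v`` image rows (y); both must be unit length and
    orthogonal to the line of sight.
    """

    name: str
    line_of_sight: tuple[float, float, float]
    u: tuple[float, float, float]
    v: tuple[float, float, float]
    pixel_size_mm: float = 0.5

    def __post_init__(self) -> None:
        los, u, v = (np.asarray(x, dtype=float) for x in (self.line_of_sight, self.u, self.v))
        for name, vec in (("line_of_sight", los), ("u", u), ("v", v)):
            if abs(np.linalg.norm(vec) - 1.0) > _ORTHO_TOL:
                raise ValueError(f"{name} must be a unit vector, got {vec}")
        if (
            abs(u @ v) > _ORTHO_TOL
            or abs(u @ los) > _ORTHO_TOL
            or abs(v @ los) > _ORTHO_TOL
        ):
            raise ValueError("in-plane basis must be orthonormal and orthogonal to the line of sight")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def los_array(self) -> np.ndarray:
        return np.asarray(self.line_of_sight, dtype=float)

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.u, dtype=float), np.asarray(self.v, dtype=float)


@dataclass(frozen=True)
class MipConfig:
    """Depth window and sampling of the projection rays."""

    depth_mm: float = 1.5
    step_mm: float | None = None  # default: min voxel spacing / 4
    interpolation: str = "trilinear"

    def __post_init__(self) -> None:
        if self.depth_mm <= 0:
            raise ValueError("depth_mm must be positive")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.interpolation not in ("nearest", "trilinear"):
            raise ValueError("interpolation must be 'nearest' or 'trilinear'")

    def resolve_step(self, spacing_mm) -> float:
        step = self.step_mm if self.step_mm is not None else min(spacing_mm) / 4.0
        if step > min(spacing_mm) / 2.0 + 1e-12:
            raise ValueError(
                f"step_mm={step} too coarse: must be <= min voxel spacing / 2 "
                f"({min(spacing_mm) / 2.0} mm)"
            )
        return step


@dataclass
class Densitogram:
    """Per-pixel maximum-HU map over the projected joint surface of one view."""

    pixels: np.ndarray        # float, NaN where surface_mask is False
    surface_mask: np.ndarray  # bool footprint of the projected joint surface
    view: ViewSpec
    depth_map: np.ndarray     # ray parameter of the first bone hit (mm), NaN off-surface
    origin_uv: tuple[float, float] = (0.0, 0.0)  # (u, v) of pixel [0, 0]

    def __post_init__(self) -> None:
        if self.pixels.shape != self.surface_mask.shape:
            raise ValueError("pixels and surface_mask must be congruent")
        if np.isfinite(self.pixels[~self.surface_mask]).any():
            raise ValueError("pixels must be NaN outside the surface footprint")

    @property
    def n_surface_pixels(self) -> int:
        return int(self.surface_mask.sum())


def make_views(
    mask: BoneMask,
    tilt_deg: float = 90.0,
    pixel_size_mm: float | None = None,
) -> tuple[ViewSpec, ViewSpec]:
    """Build the proximal view and the tilted distal view from axis labels.

    The proximal line of sight runs along the volume's declared
    proximodistal axis (into the volume); the distal view is the proximal
    frame rotated by ``tilt_deg`` about the mediolateral axis, so that with
    the default 90 degrees it looks at the ridge end faces.  The image-x
    basis is the mediolateral axis in both views, which keeps left/right
    mirroring a pure column flip.
    """
    if not 0.0 <= tilt_deg <= 180.0:
        raise ValueError(f"tilt_deg must be in [0, 180], got {tilt_deg}")
    labels = tuple(mask.axis_labels)
    try:
        i_pd = labels.index("proximodistal")
        i_ml = labels.index("mediolateral")
    except ValueError:
        raise ValueError(
            f"axis labels {labels} lack 'proximodistal'/'mediolateral'; "
            "construct ViewSpecs with explicit view vectors instead"
        ) from None
    i_dp = ({0, 1, 2} - {i_pd, i_ml}).pop()
    if pixel_size_mm is None:
        pixel_size_mm = min(mask.spacing_mm)

    e = np.eye(3)
    los_p, u_p, v_p = e[i_pd], e[i_ml], e[i_dp]
    rot = Rotation.from_rotvec(math.radians(tilt_deg) * e[i_ml])
    los_d, v_d = rot.apply(los_p), rot.apply(v_p)
    proximal = ViewSpec("proximal", tuple(los_p), tuple(u_p), tuple(v_p), pixel_size_mm)
    distal = ViewSpec("distal", tuple(los_d), tuple(u_p), tuple(v_d), pixel_size_mm)
    return proximal, distal


def mip_project(
    volume: CtVolume,
    mask: BoneMask,
    view: ViewSpec,
    cfg: MipConfig = MipConfig(),
    _chunk_px: int = 4096,
) -> Densitogram:
    """Cast parallel rays through the mask and take the depth-limited maximum.

    For each pixel of the view plane a ray is sampled at uniform steps; the
    first sample inside the mask fixes the ray parameter ``t0`` and the pixel
    value is the maximum interpolated HU over ``t in [t0, t0 + depth_mm]``
    at masked positions only.  Rays that miss the mask are background.

    With ``interpolation="nearest"`` the mask and HU lookups round to the
    nearest voxel centre (half-up, deterministic); ``"trilinear"``
    interpolates HU with order-1 splines while the mask stays nearest —
    a sample is "masked" exactly when its nearest voxel is.
    """
    if mask.mask.shape != volume.shape:
        raise ValueError("mask is not congruent with the volume")
    if not mask.mask.any():
        raise ValueError("mask is empty")
    step = cfg.resolve_step(volume.spacing_mm)
    los = view.los_array
    u, v = view.basis
    px = view.pixel_size_mm

    spacing = np.asarray(volume.spacing_mm)
    origin = np.asarray(volume.origin_mm)
    idx = np.argwhere(mask.mask)
    world = origin + idx * spacing
    uu, vv, tt = world @ u, world @ v, world @ los
    u_lo, u_hi = uu.min(), uu.max()
    v_lo, v_hi = vv.min(), vv.max()
    t_lo, t_hi = tt.min(), tt.max()

    n_u = int(round((u_hi - u_lo) / px)) + 3
    n_v = int(round((v_hi - v_lo) / px)) + 3
    u_c = (u_lo - px) + np.arange(n_u) * px
    v_c = (v_lo - px) + np.arange(n_v) * px
    pad = max(spacing)
    t_c = np.arange(t_lo - pad, t_hi + pad + step, step)

    vg, ug = np.meshgrid(v_c, u_c, indexing="ij")
    p0 = ug[..., None] * u + vg[..., None] * v  # (H, W, 3)
    p0_flat = p0.reshape(-1, 3)

    pixels = np.full(n_v * n_u, np.nan)
    depth_map = np.full(n_v * n_u, np.nan)
    surface = np.zeros(n_v * n_u, dtype=bool)

    n_t = t_c.size
    chunk = max(1, int(_chunk_px * 512 // max(n_t, 1)))
    for s in range(0, p0_flat.shape[0], chunk):
        sl = slice(s, min(s + chunk, p0_flat.shape[0]))
        pts = p0_flat[sl, None, :] + t_c[None, :, None] * los  # (P, T, 3)
        coords = (pts - origin) / spacing
        m = _sample_nearest(mask.mask, coords)
        hit = m.any(axis=1)
        if not hit.any():
            continue
        first = np.argmax(m, axis=1)
        t0 = t_c[first]
        in_window = m & (t_c[None, :] >= t0[:, None] - 1e-9) & (
            t_c[None, :] <= t0[:, None] + cfg.depth_mm + 1e-9
        )
        if cfg.interpolation == "nearest":
            hu = _sample_nearest_values(volume.voxels, coords)
        else:
            flat = coords.reshape(-1, 3).T
            hu = map_coordinates(volume.voxels, flat, order=1, mode="nearest").reshape(
                coords.shape[:2]
            )
        vals = np.where(in_window, hu, -np.inf).max(axis=1)
        out = slice(sl.start, sl.stop)
        surface[out] = hit
        pixels[out] = np.where(hit, vals, np.nan)
        depth_map[out] = np.where(hit, t0, np.nan)

    return Densitogram(
        pixels.reshape(n_v, n_u),
        surface.reshape(n_v, n_u),
        view,
        depth_map.reshape(n_v, n_u),
        origin_uv=(float(u_c[0]), float(v_c[0])),
    )


def _nearest_indices(coords: np.ndarray) -> np.ndarray:
    # deterministic half-up rounding, not banker's
    return np.floor(coords + 0.5).astype(np.intp)


def _sample_nearest(mask: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Nearest-voxel mask lookup; out-of-volume samples are background."""
    ci = _nearest_indices(coords)
    inb = np.all((ci >= 0) & (ci < np.asarray(mask.shape)), axis=-1)
    cc = np.clip(ci, 0, np.asarray(mask.shape) - 1)
    return inb & mask[cc[..., 0], cc[..., 1], cc[..., 2]]


def _sample_nearest_values(vol: np.ndarray, coords: np.ndarray) -> np.ndarray:
    ci = np.clip(_nearest_indices(coords), 0, np.asarray(vol.shape) - 1)
    return vol[ci[..., 0], ci[..., 1], ci[..., 2]]


def brute_force_mip(
    volume: CtVolume,
    mask: BoneMask,
    axis: int,
    depth_mm: float = 1.5,
    reverse: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent axis-aligned MIP oracle working directly on voxel columns.

    For every 2-D voxel column along ``axis`` (optionally traversed in
    reverse), the first masked voxel defines the surface; the result pixel is
    the maximum HU over masked voxels whose centre lies within ``depth_mm``
    of the first one.  Returns ``(pixels, footprint)`` on the full voxel
    grid of the two remaining axes, in their native index order.

    Implemented as an explicit per-column scan so it can serve as an oracle
    for :func:`mip_project`; it shares no code with the ray caster.
    """
    vox = np.moveaxis(volume.voxels, axis, 0)
    m = np.moveaxis(mask.mask, axis, 0)
    if reverse:
        vox, m = vox[::-1], m[::-1]
    sp = volume.spacing_mm[axis]
    n, h, w = vox.shape
    pixels = np.full((h, w), np.nan)
    footprint = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            col = m[:, r, c]
            hits = np.flatnonzero(col)
            if hits.size == 0:
                continue
            i0 = hits[0]
            within = hits[(hits - i0) * sp <= depth_mm + 1e-9]
            pixels[r, c] = vox[within, r, c].max()
            footprint[r, c] = True
    return pixels, footprint
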