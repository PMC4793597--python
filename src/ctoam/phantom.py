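"""Synthetic CT phantoms of a ridged, talus-like bone with known ground truth.

The phantom is two parallel half-cylinder ridges sitting on a rectangular
base block, embedded in uniform soft tissue — a deliberately simple stand-in
for the medial and lateral trochlear ridges whose projections are computable
in closed form.  The bone has a dense subchondral shell (``hu_plate``) over a
lower-density trabecular interior (``hu_trabecular``); one or more
high-density surface patches (``hu_peak``) emulate density maxima.  Additive
Gaussian voxel noise is applied last and is the only scanner effect modelled.

Axis convention (see :mod:`ctoam.volume_io`): axis 0 proximodistal (index 0
is the proximal top, where a proximal viewer looks in from), axis 1
dorsoplantar (the ridge axis; index 0 is the end face the tilted "distal"
view looks in from), axis 2 mediolateral (the ridges are separated along it,
and left/right mirroring flips it).

:class:`PhantomTruth` carries the analytic ground truth: the exact bone mask,
and, per projection view, the fraction of projected joint-surface pixels
whose ray meets a patch within the projection depth, plus the expected
30x30-grid cell of each patch.  Truth is computed by ray-marching the
*continuous* geometry (closed-form membership tests, no voxel data), so it is
independent of the voxel pipeline it validates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import DEFAULT_AXIS_LABELS, CtVolume

_GRID_N = 30  # standardised grid size used for truth coordinates


@dataclass(frozen=True)
class BoneGeometry:
    """Two parallel half-cylinder ridges on a base block, sizes in mm."""

    ridge_radius_mm: float = 6.0
    ridge_separation_mm: float = 14.0  # centre-to-centre, mediolateral
    length_mm: float = 30.0            # ridge and block length, dorsoplantar
    block_height_mm: float = 8.0       # block below the ridge axes
    margin_mm: float = 3.0             # soft-tissue margin around the bone


@dataclass(frozen=True)
class MaximumSpec:
    """A high-density surface patch on one ridge.

    The patch is the set of points of the subchondral shell (radial annulus
    ``[r - shell_thickness, r]``) whose geodesic distance on the outer ridge
    surface from the centre ``(axial_fraction, angle_deg)`` is at most
    ``patch_radius_mm``.  ``angle_deg`` is measured from the proximal apex of
    the ridge (0 = top), positive toward +mediolateral.
    """

    ridge: int                 # 0 = medial ridge (low mediolateral coord), 1 = lateral
    axial_fraction: float      # 0 (distal-view end face) .. 1 along the ridge axis
    angle_deg: float
    patch_radius_mm: float = 4.0
    hu_peak: float = 1150.0

    def validate(self) -> None:
        if self.ridge not in (0, 1):
            raise ValueError(f"ridge must be 0 or 1, got {self.ridge}")
        if not 0.0 <= self.axial_fraction <= 1.0:
            raise ValueError(f"axial_fraction must be in [0, 1], got {self.axial_fraction}")
        if self.patch_radius_mm <= 0:
            raise ValueError("patch_radius_mm must be positive")


def default_maxima() -> tuple[MaximumSpec, MaximumSpec]:
    """One patch per ridge, near the end face so both views can see them.

    The straight ridges are seen end-on by the 90 deg tilted view, so only
    surface within the projection depth of the end face appears there; the
    default axial fraction (0.03 of a 30 mm ridge = 0.9 mm) keeps each patch
    inside the default 1.5 mm depth window.  Angles lean toward the medial
    and lateral borders respectively.
    """
    return (
        MaximumSpec(ridge=0, axial_fraction=0.03, angle_deg=-25.0),
        MaximumSpec(ridge=1, axial_fraction=0.03, angle_deg=25.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic volume; the seed is mandatory."""

    seed: int
    volume_shape: tuple[int, int, int] = (48, 72, 64)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    bone_geometry: BoneGeometry = field(default_factory=BoneGeometry)
    shell_thickness_mm: float = 1.5
    hu_background: float = 50.0
    hu_trabecular: float = 400.0
    hu_plate: float = 700.0
    maxima: tuple[MaximumSpec, ...] = field(default_factory=default_maxima)
    noise_sd: float = 0.0

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("all spacings must be positive")
        if any(n < 2 for n in self.volume_shape):
            raise ValueError("volume_shape entries must be >= 2")
        if self.shell_thickness_mm <= 0:
            raise ValueError("shell_thickness_mm must be positive")
        if not self.hu_background < self.hu_trabecular < self.hu_plate:
            raise ValueError("require hu_background < hu_trabecular < hu_plate")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        g = self.bone_geometry
        if g.ridge_radius_mm <= min(self.spacing_mm):
            raise ValueError(
                f"degenerate geometry: ridge radius {g.ridge_radius_mm} mm must exceed "
                f"the voxel spacing {min(self.spacing_mm)} mm"
            )
        if g.ridge_separation_mm < 2 * g.ridge_radius_mm:
            raise ValueError("ridges overlap: separation must be >= 2 * radius")
        for m in self.maxima:
            m.validate()
            if m.hu_peak <= self.hu_plate:
                raise ValueError("patch hu_peak must exceed hu_plate")
        ext = _geometry_extents(self)
        for ax in range(3):
            if ext[ax] > self.volume_shape[ax] * self.spacing_mm[ax]:
                raise ValueError(
                    f"bone geometry ({ext[ax]:.1f} mm on axis {ax}) does not fit the "
                    f"volume ({self.volume_shape[ax] * self.spacing_mm[ax]:.1f} mm)"
                )


@dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom."""

    bone_mask: np.ndarray
    #: view name -> fraction of silhouette pixels whose ray meets any patch
    maxima_surface_fraction_per_view: dict[str, float]
    #: view name -> list of (x, y) 1..30 grid cells, one per patch (None if unseen)
    maxima_true_grid_coords: dict[str, list[tuple[int, int] | None]]
    #: view name -> per-patch silhouette fraction
    per_patch_fraction_per_view: dict[str, list[float]]


# ---------------------------------------------------------------------------
# continuous geometry


class _Geometry:
    """World-frame placement of the bone, derived from a PhantomSpec."""

    def __init__(self, spec: PhantomSpec):
        g = spec.bone_geometry
        size = np.asarray(spec.volume_shape) * np.asarray(spec.spacing_mm)
        self.r = g.ridge_radius_mm
        self.shell = spec.shell_thickness_mm
        self.length = g.length_mm
        # ridge axes run along axis 1 at height z_axis (axis 0) and
        # mediolateral centres cx (axis 2)
        self.z_top = g.margin_mm                       # proximal apex of ridges
        self.z_axis = self.z_top + self.r              # ridge axis height = block top
        self.z_bottom = self.z_axis + g.block_height_mm
        self.y0 = (size[1] - g.length_mm) / 2.0
        self.y1 = self.y0 + g.length_mm
        xc = size[2] / 2.0
        self.cx = (xc - g.ridge_separation_mm / 2.0, xc + g.ridge_separation_mm / 2.0)
        self.x0 = self.cx[0] - self.r                  # block footprint
        self.x1 = self.cx[1] + self.r
        self.maxima = spec.maxima

    def in_bone(self, p: np.ndarray) -> np.ndarray:
        """Membership of world points (..., 3) in the bone solid."""
        z, y, x = p[..., 0], p[..., 1], p[..., 2]
        in_y = (y >= self.y0) & (y <= self.y1)
        block = in_y & (x >= self.x0) & (x <= self.x1) & (z >= self.z_axis) & (z <= self.z_bottom)
        out = block
        for cx in self.cx:
            ridge = in_y & (z <= self.z_axis) & ((x - cx) ** 2 + (z - self.z_axis) ** 2 <= self.r**2)
            out = out | ridge
        return out

    def patch_membership(self, p: np.ndarray, m: MaximumSpec) -> np.ndarray:
        """Membership of world points in one patch (annulus x geodesic disc)."""
        z, y, x = p[..., 0], p[..., 1], p[..., 2]
        cx = self.cx[m.ridge]
        dz = self.z_axis - z          # >= 0 on the upper half
        dx = x - cx
        rho = np.hypot(dx, dz)
        theta = np.arctan2(dx, dz)    # 0 at the proximal apex
        y_c = self.y0 + m.axial_fraction * self.length
        arc = self.r * (theta - math.radians(m.angle_deg))
        geod = np.hypot(y - y_c, arc)
        return (
            (dz >= 0)
            & (rho <= self.r)
            & (rho >= self.r - self.shell)
            & (y >= self.y0)
            & (y <= self.y1)
            & (geod <= m.patch_radius_mm)
        )

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.z_top, self.y0, self.x0])
        hi = np.array([self.z_bottom, self.y1, self.x1])
        return lo, hi


def _geometry_extents(spec: PhantomSpec) -> np.ndarray:
    g = spec.bone_geometry
    return np.array(
        [
            g.margin_mm * 2 + g.ridge_radius_mm + g.block_height_mm,
            g.margin_mm * 2 + g.length_mm,
            g.margin_mm * 2 + g.ridge_separation_mm + 2 * g.ridge_radius_mm,
        ]
    )


# ---------------------------------------------------------------------------
# volume construction


def generate_phantom(spec: PhantomSpec) -> tuple[CtVolume, PhantomTruth]:
    """Build the voxel volume and its analytic ground truth.

    Voxel membership is decided at voxel centres.  Construction order:
    trabecular interior, subchondral shell (within ``shell_thickness_mm`` of
    the outer surface, by Euclidean distance transform), high-density
    patches, then additive Gaussian noise seeded by ``spec.seed``.  Noise is
    not truncated; downstream stages must tolerate arbitrary real HU.
    """
    spec.validate()
    geom = _Geometry(spec)
    centers = _voxel_centers(spec)
    bone = geom.in_bone(centers)
    if not bone.any():
        raise ValueError("geometry produced an empty bone mask")
    # Regularise the voxelised solid with a one-voxel closing (idempotent),
    # removing the sub-voxel crevice where the ridges meet the block; real
    # bone has no such crevices and segmentation applies the same closing.
    bone = ndimage.binary_closing(bone, structure=ndimage.generate_binary_structure(3, 1))

    hu = np.full(spec.volume_shape, spec.hu_background, dtype=np.float64)
    hu[bone] = spec.hu_trabecular
    # shell: bone voxels within shell_thickness of the nearest background voxel
    dist = ndimage.distance_transform_edt(bone, sampling=spec.spacing_mm)
    shell = bone & (dist <= spec.shell_thickness_mm)
    hu[shell] = spec.hu_plate
    for m in spec.maxima:
        hu[geom.patch_membership(centers, m) & bone] = m.hu_peak

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)

    volume = CtVolume(hu, spec.spacing_mm, (0.0, 0.0, 0.0), DEFAULT_AXIS_LABELS)
    truth = compute_truth(spec, bone_mask=bone)
    return volume, truth


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    axes = [
        (np.arange(n, dtype=np.float64)) * s
        for n, s in zip(spec.volume_shape, spec.spacing_mm)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.stack([zz, yy, xx], axis=-1)


def mirror_phantom(volume: CtVolume, axis: int | str = "mediolateral") -> CtVolume:
    """Reflect a volume along one axis (default mediolateral), HU unchanged.

    Produces the contralateral-limb counterpart of a phantom; applying it
    twice returns the original volume voxelwise.
    """
    if isinstance(axis, str):
        ax = volume.axis_index(axis)
    else:
        ax = int(axis)
        if ax not in (0, 1, 2):
            raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return CtVolume(
        np.flip(volume.voxels, axis=ax).copy(),
        volume.spacing_mm,
        volume.origin_mm,
        volume.axis_labels,
    )


# ---------------------------------------------------------------------------
# analytic ground truth (continuous-geometry ray marching)

#: canonical views: name -> (line of sight, image-x basis u, image-y basis v)
_VIEW_FRAMES = {
    "proximal": (np.array([1.0, 0, 0]), np.array([0, 0, 1.0]), np.array([0, 1.0, 0])),
    "distal": (np.array([0, 1.0, 0]), np.array([0, 0, 1.0]), np.array([-1.0, 0, 0])),
}


def compute_truth(
    spec: PhantomSpec,
    depth_mm: float = 1.5,
    pixel_size_mm: float | None = None,
    step_mm: float = 0.05,
    bone_mask: np.ndarray | None = None,
) -> PhantomTruth:
    """Ground truth for the two canonical views from continuous geometry.

    For each view an orthographic pixel grid is laid over the analytic
    silhouette; each ray is marched at ``step_mm`` through closed-form
    membership tests to find the first bone hit and whether any patch lies
    within ``depth_mm`` beyond it.  No voxel data is consulted (the voxel
    ``bone_mask`` may be passed in to avoid recomputing it).
    """
    geom = _Geometry(spec)
    if pixel_size_mm is None:
        pixel_size_mm = min(spec.spacing_mm)
    if bone_mask is None:
        bone_mask = geom.in_bone(_voxel_centers(spec))

    fractions: dict[str, float] = {}
    coords: dict[str, list[tuple[int, int] | None]] = {}
    per_patch: dict[str, list[float]] = {}
    for name, (los, u, v) in _VIEW_FRAMES.items():
        sil, patch_maps = _ray_march_view(geom, los, u, v, pixel_size_mm, depth_mm, step_mm)
        n_sil = int(sil.sum())
        any_patch = np.zeros_like(sil)
        view_coords: list[tuple[int, int] | None] = []
        view_fracs: list[float] = []
        for pm in patch_maps:
            any_patch |= pm
            view_fracs.append(pm.sum() / n_sil if n_sil else 0.0)
            view_coords.append(_grid_cell_of_map(pm, sil))
        fractions[name] = float(any_patch.sum() / n_sil) if n_sil else 0.0
        coords[name] = view_coords
        per_patch[name] = view_fracs
    return PhantomTruth(bone_mask, fractions, coords, per_patch)


def _ray_march_view(geom, los, u, v, pixel_size, depth, step):
    lo, hi = geom.bounds()
    corners = np.array(
        [[z, y, x] for z in (lo[0], hi[0]) for y in (lo[1], hi[1]) for x in (lo[2], hi[2])]
    )
    uu, vv, tt = corners @ u, corners @ v, corners @ los
    u_c = np.arange(uu.min() - pixel_size, uu.max() + pixel_size + 1e-9, pixel_size)
    v_c = np.arange(vv.min() - pixel_size, vv.max() + pixel_size + 1e-9, pixel_size)
    t_c = np.arange(tt.min() - step, tt.max() + depth + step, step)

    vg, ug = np.meshgrid(v_c, u_c, indexing="ij")
    base = ug[..., None] * u + vg[..., None] * v          # (H, W, 3)
    pts = base[:, :, None, :] + t_c[None, None, :, None] * los  # (H, W, T, 3)
    inside = geom.in_bone(pts)                            # (H, W, T)
    sil = inside.any(axis=-1)
    first = np.argmax(inside, axis=-1)                    # index of first hit
    t0 = t_c[first]
    in_window = inside & (t_c[None, None, :] >= t0[..., None]) & (
        t_c[None, None, :] <= t0[..., None] + depth + 1e-9
    )
    patch_maps = []
    for m in geom.maxima:
        pm = geom.patch_membership(pts, m)
        patch_maps.append(sil & (pm & in_window).any(axis=-1))
    return sil, patch_maps


def _grid_cell_of_map(patch_map: np.ndarray, silhouette: np.ndarray):
    """30x30 grid cell of a patch footprint's centroid, silhouette-bounded."""
    if not patch_map.any():
        return None
    rows, cols = np.nonzero(silhouette)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    pr, pc = np.nonzero(patch_map)
    cr, cc = pr.mean(), pc.mean()
    gx = _cell_index(cc, c0, c1)
    gy = _cell_index(cr, r0, r1)
    return (gx, gy)


def _cell_index(coord: float, lo: float, hi: float, n: int = _GRID_N) -> int:
    extent = hi - lo
    if extent <= 0:
        return 1
    return min(int(math.floor(n * (coord - lo) / extent)) + 1, n)


# ---------------------------------------------------------------------------
# plain-text key/value configuration


def spec_from_config(path: str | Path) -> PhantomSpec:
    """Read a PhantomSpec from a plain-text ``key = value`` file.

    Triplets are comma-separated; each ``maximum`` line adds one patch as
    ``ridge, axial_fraction, angle_deg, patch_radius_mm, hu_peak``.  Lines
    starting with ``#`` are comments.  ``seed`` is required.
    """
    scalars: dict[str, float] = {}
    triplets: dict[str, tuple] = {}
    geometry: dict[str, float] = {}
    maxima: list[MaximumSpec] = []
    geo_keys = {f.strip() for f in BoneGeometry.__dataclass_fields__}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"expected 'key = value', got: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "maximum":
            parts = [float(x) for x in value.split(",")]
            if len(parts) != 5:
                raise ValueError("maximum needs 5 values: ridge, axial, angle, radius, hu_peak")
            maxima.append(MaximumSpec(int(parts[0]), parts[1], parts[2], parts[3], parts[4]))
        elif key in ("volume_shape", "spacing_mm"):
            triplets[key] = tuple(float(x) for x in value.split(","))
        elif key in geo_keys:
            geometry[key] = float(value)
        else:
            scalars[key] = float(value)
    if "seed" not in scalars:
        raise ValueError("config must set an explicit seed")
    kwargs: dict = {"seed": int(scalars.pop("seed"))}
    if "volume_shape" in triplets:
        kwargs["volume_shape"] = tuple(int(x) for x in triplets["volume_shape"])
    if "spacing_mm" in triplets:
        kwargs["spacing_mm"] = triplets["spacing_mm"]
    if geometry:
        kwargs["bone_geometry"] = BoneGeometry(**geometry)
    if maxima:
        kwargs["maxima"] = tuple(maxima)
    kwargs.update(scalars)
    return PhantomSpec(**kwargs)
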