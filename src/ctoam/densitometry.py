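"""Densitogram quantisation, density-maximum detection and the MAR statistic.

The projected maximum-HU map is rendered on a fixed false-colour scale
(200-1200 HU in ten 100-HU bands) and, for quantification, converted to
8-bit (256 levels over the same window) and split equally into eight bins of
32 levels each.  A *density maximum* is an 8-connected region of surface
pixels falling in the two highest bins.  Its location is standardised on a
30x30 grid stretched over the joint-surface bounding box, and its size is
summarised by the maximum area ratio

    MAR = 100 * (pixels of the density maximum) / (pixels of the joint surface)

so that joints of different absolute size can be compared.  Right-limb grid
coordinates can be mirrored onto the left-limb frame for pooled summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .projection import Densitogram

# ---------------------------------------------------------------------------
# false-colour scale

#: Band colours from the highest-density band down to the lowest.
COLOURS_DESCENDING = (
    "black",
    "dark red",
    "light red",
    "orange",
    "yellow",
    "dark green",
    "light green",
    "dark blue",
    "light blue",
    "white",
)

#: RGB rendering of the named bands, for PNG export.
COLOUR_RGB = {
    "black": (0, 0, 0),
    "dark red": (139, 0, 0),
    "light red": (255, 102, 102),
    "orange": (255, 165, 0),
    "yellow": (255, 255, 0),
    "dark green": (0, 100, 0),
    "light green": (144, 238, 144),
    "dark blue": (0, 0, 139),
    "light blue": (173, 216, 230),
    "white": (255, 255, 255),
}


@dataclass(frozen=True)
class ColourScale:
    """Fixed HU window divided into equal bands, one colour per band."""

    lower_hu: float = 200.0
    upper_hu: float = 1200.0
    band_hu: float = 100.0
    colours: tuple[str, ...] = COLOURS_DESCENDING

    def __post_init__(self) -> None:
        n_bands = (self.upper_hu - self.lower_hu) / self.band_hu
        if abs(n_bands - len(self.colours)) > 1e-9:
            raise ValueError(
                f"window/band mismatch: {n_bands} bands for {len(self.colours)} colours"
            )


def to_false_colour(d: Densitogram, scale: ColourScale = ColourScale()) -> np.ndarray:
    """Assign each surface pixel the colour of its HU band.

    Bands are half-open ``[low, high)`` intervals; values below the window
    clamp to the lowest band, values at or above its top to the highest.
    Off-surface pixels get the empty string.  Returns an (H, W) array of
    colour names (object dtype).
    """
    n = len(scale.colours)
    band = np.floor((d.pixels - scale.lower_hu) / scale.band_hu)
    band = np.clip(np.nan_to_num(band, nan=0.0), 0, n - 1).astype(int)
    ascending = np.asarray(scale.colours[::-1], dtype=object)
    out = np.where(d.surface_mask, ascending[band], "")
    return out


def false_colour_rgb(d: Densitogram, scale: ColourScale = ColourScale()) -> np.ndarray:
    """(H, W, 3) uint8 rendering of :func:`to_false_colour` (mid-grey off-surface)."""
    names = to_false_colour(d, scale)
    out = np.full(names.shape + (3,), 128, dtype=np.uint8)
    for name, rgb in COLOUR_RGB.items():
        out[names == name] = rgb
    return out


# ---------------------------------------------------------------------------
# 8-bit conversion and binning

N_BINS = 8
LEVELS_PER_BIN = 256 // N_BINS  # 32


@dataclass
class BinnedDensitogram:
    """Densitogram quantised to 8-bit then to eight equal bins."""

    eight_bit: np.ndarray  # int, 0..255 on surface pixels, 0 elsewhere
    bin_index: np.ndarray  # int, 0..7 on surface pixels, 0 elsewhere
    parent: Densitogram

    @property
    def surface_mask(self) -> np.ndarray:
        return self.parent.surface_mask

    def bin_counts(self) -> np.ndarray:
        """Surface-pixel count per bin, length 8; sums to the footprint size."""
        return np.bincount(self.bin_index[self.surface_mask], minlength=N_BINS)


def to_8bit(
    d: Densitogram,
    lower_hu: float = 200.0,
    upper_hu: float = 1200.0,
    per_image: bool = False,
) -> BinnedDensitogram:
    """Quantise HU to 256 levels over a window, then into eight equal bins.

    ``eight_bit = floor(255 * clamp((HU - lower) / (upper - lower), 0, 1))``
    and ``bin_index = eight_bit // 32`` (bin 7 spans levels 224-255).  The
    default fixed 200-1200 HU window matches the false-colour scale and
    keeps the bins absolute across subjects; ``per_image=True`` instead
    stretches the window to the densitogram's own min/max.
    """
    if per_image:
        vals = d.pixels[d.surface_mask]
        lower_hu, upper_hu = float(vals.min()), float(vals.max())
    if not lower_hu < upper_hu:
        raise ValueError(f"need lower_hu < upper_hu, got {lower_hu}, {upper_hu}")
    frac = np.clip((np.nan_to_num(d.pixels, nan=lower_hu) - lower_hu) / (upper_hu - lower_hu), 0.0, 1.0)
    eight_bit = np.floor(255.0 * frac).astype(np.int64)
    eight_bit[~d.surface_mask] = 0
    return BinnedDensitogram(eight_bit, eight_bit // LEVELS_PER_BIN, d)


# ---------------------------------------------------------------------------
# density maxima

#: lowest bin counting toward a density maximum (two highest of eight)
MAXIMUM_BIN_THRESHOLD = N_BINS - 2

DEFAULT_MIN_AREA = 5


@dataclass
class DensityMaximum:
    """One 8-connected region of top-two-bin surface pixels."""

    pixel_mask: np.ndarray          # bool, same shape as the densitogram
    area_pixels: int
    centroid_rc: tuple[float, float]  # (row, col) in pixel coordinates
    is_primary: bool = False
    grid_xy: tuple[int, int] | None = None


def detect_maxima(
    b: BinnedDensitogram, min_area: int = DEFAULT_MIN_AREA
) -> list[DensityMaximum]:
    """Find density maxima: top-two-bin pixels grouped 8-connectedly.

    Components smaller than ``min_area`` pixels are discarded (default 5,
    suppressing single-pixel noise).  The largest survivor is flagged
    primary; ties break toward the smaller centroid row, then column.
    Returns maxima sorted primary-first then by the same key; an empty list
    is a valid outcome.
    """
    hot = b.surface_mask & (b.bin_index >= MAXIMUM_BIN_THRESHOLD)
    labels = measure.label(hot, connectivity=2)
    maxima: list[DensityMaximum] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        maxima.append(
            DensityMaximum(
                pixel_mask=labels == region.label,
                area_pixels=int(region.area),
                centroid_rc=(float(region.centroid[0]), float(region.centroid[1])),
            )
        )
    maxima.sort(key=lambda m: (-m.area_pixels, m.centroid_rc[0], m.centroid_rc[1]))
    if maxima:
        maxima[0].is_primary = True
    return maxima


# ---------------------------------------------------------------------------
# standardised grid

GRID_N = 30


@dataclass(frozen=True)
class GridOverlay:
    """A 30x30 grid stretched over the joint-surface bounding box.

    Cells are indexed 1..30 in x (columns) and y (rows); every surface pixel
    maps to exactly one cell via floor division, with the far edges clamped
    into cell 30.
    """

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    n_cells: int = GRID_N

    def cell_of(self, row: float, col: float) -> tuple[int, int]:
        """(x, y) cell of a pixel-space point; x from columns, y from rows."""
        return (
            _cell_index(col, self.col_min, self.col_max, self.n_cells),
            _cell_index(row, self.row_min, self.row_max, self.n_cells),
        )


def _cell_index(coord: float, lo: float, hi: float, n: int) -> int:
    extent = hi - lo
    if extent <= 0:
        raise ValueError("zero-extent footprint: cannot place the grid")
    return min(int(np.floor(n * (coord - lo) / extent)) + 1, n)


def overlay_grid(surface_mask: np.ndarray, n_cells: int = GRID_N) -> GridOverlay:
    """Fit the grid tightly over the footprint so the whole surface fits inside."""
    mask = np.asarray(surface_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty surface footprint")
    rows, cols = np.nonzero(mask)
    g = GridOverlay(
        int(rows.min()), int(rows.max()), int(cols.min()), int(cols.max()), n_cells
    )
    if g.row_max == g.row_min or g.col_max == g.col_min:
        raise ValueError("zero-extent footprint: cannot place the grid")
    return g


def locate(m: DensityMaximum, g: GridOverlay) -> tuple[int, int]:
    """Grid cell containing the maximum's area centroid; stored on the maximum."""
    m.grid_xy = g.cell_of(*m.centroid_rc)
    return m.grid_xy


def mirror_coords(grid_xy: tuple[int, int], side: str, n_cells: int = GRID_N) -> tuple[int, int]:
    """Mirror right-limb grid x onto the left-limb frame: x -> n+1-x, y kept."""
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    x, y = grid_xy
    if side == "right":
        return (n_cells + 1 - x, y)
    return (x, y)


# ---------------------------------------------------------------------------
# MAR


@dataclass
class MarResult:
    """Maximum-area-ratio record for one joint, side and view."""

    subject_id: str
    side: str
    view: str
    total_surface_pixels: int
    max_area_pixels: int
    mar: float  # percent

    def __post_init__(self) -> None:
        if not 0.0 <= self.mar <= 100.0:
            raise ValueError(f"MAR must be within [0, 100], got {self.mar}")


def compute_mar(
    maxima: list[DensityMaximum],
    surface_mask: np.ndarray,
    subject_id: str = "",
    side: str = "left",
    view: str = "proximal",
    primary_only: bool = False,
) -> MarResult:
    """MAR in percent: density-maximum pixels over joint-surface pixels.

    By default the numerator pools every retained maximum (the joint may
    carry a focal additional maximum besides the primary one);
    ``primary_only=True`` restricts it to the largest region.
    """
    total = int(np.asarray(surface_mask, dtype=bool).sum())
    if total == 0:
        raise ValueError("empty joint surface")
    if primary_only:
        pool = [m for m in maxima if m.is_primary]
    else:
        pool = maxima
    max_pixels = int(sum(m.area_pixels for m in pool))
    return MarResult(
        subject_id=subject_id,
        side=side,
        view=view,
        total_surface_pixels=total,
        max_area_pixels=max_pixels,
        mar=100.0 * max_pixels / total,
    )
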