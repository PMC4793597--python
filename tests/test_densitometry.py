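"""False-colour scale, 8-bit binning, maxima detection, grid mapping and MAR."""

from collections import deque

import numpy as np
import pytest

import ctoam
from ctoam.densitometry import GridOverlay, _cell_index
from ctoam.projection import Densitogram, ViewSpec


def _densitogram(values):
    """Wrap a 2-D HU array (NaN = off-surface) as a Densitogram."""
    arr = np.asarray(values, dtype=float)
    surface = np.isfinite(arr)
    view = ViewSpec("proximal", (1, 0, 0), (0, 0, 1), (0, 1, 0), 1.0)
    depth = np.where(surface, 0.0, np.nan)
    return Densitogram(arr, surface, view, depth)


class TestFalseColour:
    @pytest.mark.parametrize(
        "hu,colour",
        [
            (1150.0, "black"),     # highest band
            (250.0, "white"),      # lowest band of the descending scale
            (650.0, "dark green"),  # fifth 100-HU band from the top
            (199.9, "white"),      # below the window clamps low
            (1500.0, "black"),     # above the window clamps high
            (300.0, "light blue"),  # band edges belong to the upper band
        ],
    )
    def test_band_assignment(self, hu, colour):
        d = _densitogram([[hu]])
        assert ctoam.to_false_colour(d)[0, 0] == colour

    def test_scale_invariant_checked(self):
        with pytest.raises(ValueError, match="band"):
            ctoam.ColourScale(lower_hu=0, upper_hu=1200, band_hu=100)

    def test_rgb_rendering_marks_off_surface_grey(self):
        d = _densitogram([[1150.0, np.nan]])
        rgb = ctoam.false_colour_rgb(d)
        assert tuple(rgb[0, 0]) == (0, 0, 0)
        assert tuple(rgb[0, 1]) == (128, 128, 128)


class TestTo8Bit:
    @pytest.mark.parametrize(
        "hu,eight_bit,bin_index",
        [
            (200.0, 0, 0),     # lower endpoint
            (1200.0, 255, 7),  # upper endpoint
            (711.0, 130, 4),   # floor(255 * 511/1000) = 130 -> bin 4
            (100.0, 0, 0),     # clamps below
            (953.0, 192, 6),   # first level of the two highest bins
        ],
    )
    def test_quantisation(self, hu, eight_bit, bin_index):
        b = ctoam.to_8bit(_densitogram([[hu]]))
        assert b.eight_bit[0, 0] == eight_bit
        assert b.bin_index[0, 0] == bin_index

    def test_monotone_in_hu_and_bins_every_32_levels(self):
        hus = np.linspace(-100, 1500, 801)
        b = ctoam.to_8bit(_densitogram([hus]))
        eb = b.eight_bit[0]
        assert np.all(np.diff(eb) >= 0)
        np.testing.assert_array_equal(b.bin_index[0], eb // 32)

    def test_per_image_window_stretches_to_min_max(self):
        b = ctoam.to_8bit(_densitogram([[400.0, 600.0, 800.0]]), per_image=True)
        np.testing.assert_array_equal(b.eight_bit[0], [0, 127, 255])

    def test_conservation_bin_counts_sum_to_footprint(self, noiseless_analysis):
        for va in noiseless_analysis.values():
            counts = va.binned.bin_counts()
            assert counts.sum() == va.densitogram.n_surface_pixels


def _bfs_regions(hot):
    """Brute-force 8-connected 2-D labelling (test oracle)."""
    hot = np.asarray(hot, dtype=bool)
    seen = np.zeros_like(hot)
    regions = []
    for start in zip(*np.nonzero(hot)):
        if seen[start]:
            continue
        comp, queue = [], deque([start])
        seen[start] = True
        while queue:
            r, c = queue.popleft()
            comp.append((r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if (
                        0 <= q[0] < hot.shape[0]
                        and 0 <= q[1] < hot.shape[1]
                        and hot[q]
                        and not seen[q]
                    ):
                        seen[q] = True
                        queue.append(q)
        regions.append(comp)
    return regions


class TestDetectMaxima:
    def test_all_low_bins_yield_empty_list(self):
        b = ctoam.to_8bit(_densitogram(np.full((5, 5), 300.0)))
        assert ctoam.detect_maxima(b) == []

    def test_single_patch_is_primary_with_exact_area(self):
        arr = np.full((6, 6), 300.0)
        arr[1, 1:4] = 1150.0
        arr[2, 2:4] = 1150.0  # 5 pixels, 8-connected
        maxima = ctoam.detect_maxima(ctoam.to_8bit(_densitogram(arr)))
        assert len(maxima) == 1
        m = maxima[0]
        assert m.is_primary and m.area_pixels == 5

    def test_two_patches_largest_primary_against_bfs_oracle(self):
        arr = np.full((12, 14), 300.0)
        arr[1:4, 1:5] = 1000.0  # 12 px, bin 6
        arr[8:9, 6:13] = 1150.0  # 7 px, bin 7
        b = ctoam.to_8bit(_densitogram(arr))
        maxima = ctoam.detect_maxima(b)
        oracle = sorted(_bfs_regions(arr >= 953.0), key=len, reverse=True)
        assert [m.area_pixels for m in maxima] == [len(r) for r in oracle] == [12, 7]
        assert maxima[0].is_primary and not maxima[1].is_primary

    def test_min_area_suppresses_speckle(self):
        arr = np.full((6, 6), 300.0)
        arr[0, 0] = 1200.0
        assert ctoam.detect_maxima(ctoam.to_8bit(_densitogram(arr)), min_area=5) == []
        assert len(ctoam.detect_maxima(ctoam.to_8bit(_densitogram(arr)), min_area=1)) == 1

    def test_area_tie_broken_by_centroid_row_then_column(self):
        arr = np.full((9, 9), 300.0)
        arr[6:8, 0:3] = 1150.0  # lower-left, 6 px
        arr[0:2, 5:8] = 1150.0  # upper-right, 6 px
        maxima = ctoam.detect_maxima(ctoam.to_8bit(_densitogram(arr)))
        assert maxima[0].is_primary
        assert maxima[0].centroid_rc[0] < maxima[1].centroid_rc[0]


class TestGrid:
    def _grid(self):
        mask = np.zeros((40, 50), dtype=bool)
        mask[5:35, 10:40] = True  # rows 5..34, cols 10..39
        return ctoam.overlay_grid(mask)

    def test_bbox_minimum_corner_maps_to_cell_1_1(self):
        g = self._grid()
        assert g.cell_of(5.0, 10.0) == (1, 1)

    def test_far_edge_clamps_to_cell_30(self):
        g = self._grid()
        assert g.cell_of(34.0, 39.0) == (30, 30)

    def test_fractional_position_example(self):
        # centroid at 37% of width and 62% of height -> cells (12, 19)
        assert _cell_index(0.37, 0.0, 1.0, 30) == 12
        assert _cell_index(0.62, 0.0, 1.0, 30) == 19

    def test_every_surface_pixel_maps_to_exactly_one_cell(self):
        g = self._grid()
        for row, col in [(5, 10), (20, 25), (34, 39), (7, 38)]:
            x, y = g.cell_of(row, col)
            assert 1 <= x <= 30 and 1 <= y <= 30

    def test_zero_extent_footprint_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        with pytest.raises(ValueError, match="extent|footprint"):
            ctoam.overlay_grid(mask)

    def test_locate_stores_cell_on_maximum(self):
        arr = np.full((30, 30), 300.0)
        arr[2:5, 2:5] = 1150.0
        b = ctoam.to_8bit(_densitogram(arr))
        maxima = ctoam.detect_maxima(b)
        g = ctoam.overlay_grid(b.surface_mask)
        xy = ctoam.locate(maxima[0], g)
        assert maxima[0].grid_xy == xy == (4, 4)


class TestMar:
    def test_direct_ratio_25_percent(self):
        arr = np.full((10, 10), 300.0)
        arr[0:5, 0:5] = 1150.0
        b = ctoam.to_8bit(_densitogram(arr))
        mar = ctoam.compute_mar(ctoam.detect_maxima(b), b.surface_mask)
        assert mar.total_surface_pixels == 100
        assert mar.max_area_pixels == 25
        assert mar.mar == 25.0

    def test_no_maxima_gives_zero(self):
        b = ctoam.to_8bit(_densitogram(np.full((4, 4), 300.0)))
        assert ctoam.compute_mar([], b.surface_mask).mar == 0.0

    def test_primary_only_mode_excludes_secondary_regions(self):
        arr = np.full((12, 14), 300.0)
        arr[1:4, 1:5] = 1000.0
        arr[8:9, 6:13] = 1150.0
        b = ctoam.to_8bit(_densitogram(arr))
        maxima = ctoam.detect_maxima(b)
        pooled = ctoam.compute_mar(maxima, b.surface_mask)
        primary = ctoam.compute_mar(maxima, b.surface_mask, primary_only=True)
        assert pooled.max_area_pixels == 19 and primary.max_area_pixels == 12

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ctoam.compute_mar([], np.zeros((3, 3), dtype=bool))

    def test_invariant_under_quarter_rotation(self):
        rng = np.random.default_rng(5)
        arr = np.where(rng.random((20, 20)) < 0.8, rng.uniform(200, 1200, (20, 20)), np.nan)
        b = ctoam.to_8bit(_densitogram(arr))
        mar = ctoam.compute_mar(ctoam.detect_maxima(b), b.surface_mask)
        b_rot = ctoam.to_8bit(_densitogram(np.rot90(arr)))
        mar_rot = ctoam.compute_mar(ctoam.detect_maxima(b_rot), b_rot.surface_mask)
        assert mar.mar == mar_rot.mar


class TestMirrorCoords:
    @pytest.mark.parametrize(
        "side,xy,expected",
        [
            ("right", (1, 10), (30, 10)),
            ("right", (15, 7), (16, 7)),
            ("right", (30, 1), (1, 1)),
            ("left", (4, 4), (4, 4)),
        ],
    )
    def test_reflection_rule(self, side, xy, expected):
        assert ctoam.mirror_coords(xy, side) == expected

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError):
            ctoam.mirror_coords((1, 1), "bilateral")
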