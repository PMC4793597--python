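"""View construction and the depth-limited maximum-intensity projection."""

import numpy as np
import pytest

import ctoam
from ctoam.segmentation import BoneMask

from conftest import axis_view, random_masked_volume


def _column_volume(hus, spacing=1.0):
    """A single masked voxel column along axis 0 embedded in background."""
    vox = np.zeros((len(hus) + 2, 3, 3))
    mask = np.zeros_like(vox, dtype=bool)
    for i, h in enumerate(hus):
        vox[i + 1, 1, 1] = h
        mask[i + 1, 1, 1] = True
    vol = ctoam.CtVolume(vox, (spacing,) * 3)
    return vol, BoneMask(mask, 0.0, "all", vol.spacing_mm, vol.axis_labels)


class TestMakeViews:
    def test_default_tilt_90_gives_orthogonal_lines_of_sight(self, noiseless_phantom):
        _, volume, truth = noiseless_phantom
        mask = ctoam.segment_bone(volume)
        proximal, distal = ctoam.make_views(mask)
        assert proximal.los_array @ distal.los_array == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(proximal.los_array, [1, 0, 0])
        np.testing.assert_allclose(distal.los_array, [0, 1, 0], atol=1e-12)
        # the mediolateral axis spans image columns in both views
        np.testing.assert_allclose(proximal.u, distal.u)

    def test_tilt_0_and_180_limits(self, noiseless_phantom):
        _, volume, _ = noiseless_phantom
        mask = ctoam.segment_bone(volume)
        p0, d0 = ctoam.make_views(mask, tilt_deg=0.0)
        np.testing.assert_allclose(p0.los_array, d0.los_array, atol=1e-12)
        p180, d180 = ctoam.make_views(mask, tilt_deg=180.0)
        np.testing.assert_allclose(p180.los_array, -d180.los_array, atol=1e-12)

    def test_missing_axis_labels_demand_explicit_vectors(self, noiseless_phantom):
        _, volume, _ = noiseless_phantom
        mask = ctoam.segment_bone(volume)
        mask.axis_labels = ("a", "b", "c")
        with pytest.raises(ValueError, match="explicit view vectors"):
            ctoam.make_views(mask)

    def test_non_orthonormal_basis_rejected(self):
        with pytest.raises(ValueError, match="orthonormal|unit"):
            ctoam.ViewSpec("bad", (1, 0, 0), (1, 0, 0), (0, 0, 1))
        with pytest.raises(ValueError, match="unit"):
            ctoam.ViewSpec("bad", (2, 0, 0), (0, 1, 0), (0, 0, 1))


class TestMipProject:
    def test_uniform_bone_projects_constant_500(self):
        vol, mask = _column_volume([500.0] * 5)
        d = ctoam.mip_project(vol, mask, axis_view(0), ctoam.MipConfig(2.0, 0.5, "nearest"))
        assert d.n_surface_pixels == 1
        assert d.pixels[d.surface_mask] == pytest.approx(500.0)

    def test_depth_window_takes_max_of_300_800_400(self):
        # column HU 300, 800, 400 at 1 mm spacing: depth 3 mm spans all three
        vol, mask = _column_volume([300.0, 800.0, 400.0])
        d = ctoam.mip_project(vol, mask, axis_view(0), ctoam.MipConfig(3.0, 0.25, "nearest"))
        assert d.pixels[d.surface_mask] == pytest.approx(800.0)

    def test_single_voxel_depth_sees_only_first_surface_voxel(self):
        vol, mask = _column_volume([300.0, 800.0, 400.0])
        d = ctoam.mip_project(vol, mask, axis_view(0), ctoam.MipConfig(0.4, 0.2, "nearest"))
        assert d.pixels[d.surface_mask] == pytest.approx(300.0)

    def test_rays_missing_the_mask_are_background(self):
        vol, mask = _column_volume([500.0, 500.0])
        d = ctoam.mip_project(vol, mask, axis_view(0), ctoam.MipConfig(1.0, 0.25, "nearest"))
        assert d.surface_mask.sum() == 1
        assert np.isnan(d.pixels[~d.surface_mask]).all()

    def test_empty_or_incongruent_mask_rejected(self, noiseless_phantom):
        _, volume, _ = noiseless_phantom
        small = BoneMask(np.ones((4, 4, 4), bool), 0.0, "all", volume.spacing_mm, volume.axis_labels)
        with pytest.raises(ValueError, match="congruent"):
            ctoam.mip_project(volume, small, axis_view(0))

    def test_step_coarser_than_half_spacing_rejected(self):
        vol, mask = _column_volume([500.0])
        with pytest.raises(ValueError, match="step"):
            ctoam.mip_project(vol, mask, axis_view(0), ctoam.MipConfig(1.5, 0.9))

    @pytest.mark.parametrize("trial", range(4))
    def test_monotone_in_depth(self, trial):
        """For fixed rays, the MIP pixel value never decreases with depth."""
        rng = np.random.default_rng(100 + trial)
        vol, mask = random_masked_volume(rng)
        view = axis_view(trial % 3)
        prev = None
        for depth in (0.5, 1.5, 3.0, 6.0):
            d = ctoam.mip_project(vol, mask, view, ctoam.MipConfig(depth, 0.25, "nearest"))
            if prev is not None:
                both = prev.surface_mask & d.surface_mask
                np.testing.assert_array_equal(prev.surface_mask, d.surface_mask)
                assert np.all(d.pixels[both] >= prev.pixels[both] - 1e-12)
            prev = d

    def test_halving_step_bounded_by_adjacent_voxel_difference(self):
        """Sampling stability: halving step_mm perturbs pixels by at most the
        largest HU jump between adjacent voxels."""
        rng = np.random.default_rng(7)
        vol, mask = random_masked_volume(rng, n=12)
        view = axis_view(0)
        coarse = ctoam.mip_project(vol, mask, view, ctoam.MipConfig(2.0, 0.5, "trilinear"))
        fine = ctoam.mip_project(vol, mask, view, ctoam.MipConfig(2.0, 0.25, "trilinear"))
        bound = max(
            np.abs(np.diff(vol.voxels, axis=a)).max() for a in range(3)
        )
        both = coarse.surface_mask & fine.surface_mask
        assert np.abs(coarse.pixels[both] - fine.pixels[both]).max() <= bound + 1e-9

    def test_phantom_silhouette_matches_analytic_footprint(self, noiseless_phantom):
        """Projected footprint of the noiseless phantom agrees with the closed-form
        silhouette to within a one-pixel boundary band."""
        from ctoam.phantom import _Geometry, _VIEW_FRAMES
        import ctoam.phantom as ph

        spec, volume, _ = noiseless_phantom
        mask = ctoam.segment_bone(volume)
        views = ctoam.make_views(mask)
        geom = _Geometry(spec)
        for view in views:
            d = ctoam.mip_project(volume, mask, view, ctoam.MipConfig(1.5))
            los, u, v = _VIEW_FRAMES[view.name]
            sil, _ = ph._ray_march_view(geom, los, u, v, view.pixel_size_mm, 1.5, 0.1)
            # compare areas: discrepancy bounded by a 1-pixel band on the perimeter
            from scipy import ndimage as ndi

            perimeter = (sil & ~ndi.binary_erosion(sil)).sum()
            assert abs(int(d.surface_mask.sum()) - int(sil.sum())) <= 2 * perimeter
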