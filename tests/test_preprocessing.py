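"""Harmonic inpainting, Poisson noise, 2D shifting, 3D marker removal."""

import numpy as np
import pytest

import kvtrack as kt
from kvtrack.preprocessing import marker_footprint_2d
from kvtrack.projection import ProjectionImage
from kvtrack.volumes import VoxelVolume


def make_image(values, pitch=1.0, kind="kv"):
    return ProjectionImage(np.asarray(values, float), pitch, 0.0, kind)


def interior_mask(shape, sl):
    m = np.zeros(shape, dtype=bool)
    m[sl] = True
    return m


class TestInpaintRegions:
    def test_constant_image_is_unchanged(self):
        img = make_image(np.full((20, 20), 3.7))
        mask = interior_mask((20, 20), (slice(5, 12), slice(6, 14)))
        out = kt.inpaint_regions(img, mask)
        assert np.allclose(out.values, 3.7)

    def test_linear_ramp_is_restored_exactly(self):
        ramp = np.add.outer(np.linspace(0, 1, 24), np.linspace(0, 2, 24))
        img = make_image(ramp)
        mask = interior_mask((24, 24), (slice(8, 16), slice(4, 18)))
        out = kt.inpaint_regions(img, mask)
        assert np.allclose(out.values, ramp, atol=1e-9)

    def test_mean_value_property_and_maximum_principle(self, rng):
        img = make_image(rng.random((30, 30)))
        mask = interior_mask((30, 30), (slice(10, 20), slice(12, 22)))
        out = kt.inpaint_regions(img, mask)
        v = out.values
        # every masked pixel equals the mean of its 4-neighbours
        for r, c in np.argwhere(mask):
            nb = (v[r - 1, c] + v[r + 1, c] + v[r, c - 1] + v[r, c + 1]) / 4.0
            assert v[r, c] == pytest.approx(nb, abs=1e-8)
        # and stays within the range of the boundary values
        ring = np.zeros_like(mask)
        ring[9:21, 11:23] = True
        boundary_vals = v[ring & ~mask]
        assert v[mask].min() >= boundary_vals.min() - 1e-9
        assert v[mask].max() <= boundary_vals.max() + 1e-9

    def test_unmasked_pixels_are_untouched(self, rng):
        img = make_image(rng.random((16, 16)))
        mask = interior_mask((16, 16), (slice(6, 10), slice(6, 10)))
        out = kt.inpaint_regions(img, mask)
        assert np.array_equal(out.values[~mask], img.values[~mask])

    def test_inpainting_is_idempotent(self, rng):
        img = make_image(rng.random((16, 16)))
        mask = interior_mask((16, 16), (slice(4, 9), slice(5, 11)))
        once = kt.inpaint_regions(img, mask)
        twice = kt.inpaint_regions(once, mask)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_mask_touching_border_is_rejected(self, rng):
        img = make_image(rng.random((10, 10)))
        mask = interior_mask((10, 10), (slice(0, 3), slice(2, 5)))
        with pytest.raises(ValueError, match="border"):
            kt.inpaint_regions(img, mask)

    def test_marker_removal_end_to_end(self, marker_phantom, geom64):
        """After embedding, projecting and inpainting, the marker footprint
        deviates from the marker-free projection by < 5% of dynamic range."""
        ct, _, markers, spec = marker_phantom
        mu = spec.tissue_attenuations["marker"]
        ct_m = kt.embed_markers(ct, markers, spec.marker_radius, mu)
        for angle in (20.0, 155.0):
            clean = kt.forward_project(ct, geom64, angle)
            dirty = kt.forward_project(ct_m, geom64, angle)
            foot = marker_footprint_2d(markers, geom64, angle, spec.marker_radius)
            assert foot.any()
            # markers are visible before inpainting ...
            assert (dirty.values - clean.values)[foot].max() > 0.1
            filled = kt.inpaint_regions(dirty, foot)
            dyn = clean.values.max() - clean.values.min()
            # ... and no longer visible afterwards
            assert np.abs(filled.values - clean.values)[foot].max() < 0.05 * dyn


class TestAddPoissonNoise:
    def test_zero_pixels_stay_zero(self, rng):
        img = make_image(np.zeros((8, 8)))
        img.values[2, 2] = 1.0
        out = kt.add_poisson_noise(img, 1000, rng)
        assert out.values[0, 0] == 0.0

    def test_mean_is_unbiased(self, rng):
        img = make_image([[4.0, 2.0]])
        draws = np.array(
            [kt.add_poisson_noise(img, 500, rng).values[0, 1] for _ in range(10_000)]
        )
        se = np.sqrt(2.0 / (500 / 2.0)) / np.sqrt(10_000)  # var = value/(N/max)
        assert abs(draws.mean() - 2.0) < 3 * se

    def test_relative_noise_shrinks_with_photon_count(self, rng):
        img = make_image(np.full((50, 50), 1.0))
        lo = kt.add_poisson_noise(img, 100, rng).values.std()
        hi = kt.add_poisson_noise(img, 10_000, rng).values.std()
        assert hi < lo / 5.0  # expect factor 10

    def test_negative_image_is_rejected(self, rng):
        img = make_image(np.zeros((4, 4)))
        img.values[0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            kt.add_poisson_noise(img, 100, rng)


class TestShiftImage:
    def test_zero_shift_is_identity(self, rng):
        img = make_image(rng.random((12, 12)))
        out = kt.shift_image(img, (0.0, 0.0))
        assert np.allclose(out.values, img.values)

    def test_integer_pixel_shift_is_exact_roll(self, rng):
        img = make_image(rng.random((12, 12)), pitch=2.0)
        out = kt.shift_image(img, (4.0, -2.0))  # +2 cols, -1 row
        expected = np.zeros_like(img.values)
        expected[:-1, 2:] = img.values[1:, :-2]
        assert np.allclose(out.values, expected, atol=1e-12)

    def test_mask_centroid_moves_by_the_shift(self):
        vals = np.zeros((20, 20))
        vals[8:12, 5:9] = 1.0
        img = make_image(vals, pitch=1.0, kind="mask")
        out = kt.shift_image(img, (3.0, 2.0))
        r0, c0 = np.nonzero(vals)
        r1, c1 = np.nonzero(out.values > 0.5)
        assert c1.mean() - c0.mean() == pytest.approx(3.0)
        assert r1.mean() - r0.mean() == pytest.approx(2.0)

    def test_shift_beyond_extent_is_rejected(self, rng):
        img = make_image(rng.random((8, 8)))
        with pytest.raises(ValueError, match="extent"):
            kt.shift_image(img, (100.0, 0.0))


class TestMaskMarkers3D:
    def test_constant_volume_is_unchanged(self):
        vol = VoxelVolume(np.full((12, 12, 12), 2.0), 2.0)
        out = kt.mask_markers_3d(vol, [np.zeros(3)], 2.5)
        assert np.allclose(out.values, 2.0)

    def test_embedded_marker_in_linear_field_is_removed(self):
        # harmonic fill restores affine backgrounds exactly
        vol = VoxelVolume(np.zeros((16, 16, 16)), 2.0)
        x, y, z = vol.voxel_centres()
        vol.values = (
            0.01 * x[:, None, None] + 0.02 * y[None, :, None] + 0.005 * z[None, None, :] + 2.0
        )
        marked = kt.embed_markers(vol, [np.zeros(3)], 2.5, 50.0)
        assert (marked.values != vol.values).any()
        restored = kt.mask_markers_3d(marked, [np.zeros(3)], 2.5)
        assert np.allclose(restored.values, vol.values, atol=1e-6)

    def test_unmasked_voxels_are_bit_identical(self, phantom):
        ct, _, _ = phantom
        markers = [np.array([5.0, 0.0, 0.0])]
        out = kt.mask_markers_3d(ct, markers, 4.0)
        changed = out.values != ct.values
        d2 = sum(
            (ax.reshape([-1 if i == j else 1 for j in range(3)]) - markers[0][i]) ** 2
            for i, ax in enumerate(ct.voxel_centres())
        )
        assert changed.any()
        assert not changed[d2 > 4.0**2].any()

    def test_marker_outside_grid_is_rejected(self, phantom):
        ct, _, _ = phantom
        with pytest.raises(ValueError, match="outside"):
            kt.mask_markers_3d(ct, [np.array([999.0, 0, 0])], 1.0)

    def test_marker_region_touching_boundary_is_rejected(self):
        vol = VoxelVolume(np.ones((8, 8, 8)), 2.0)
        lo, _ = vol.world_extent()
        with pytest.raises(ValueError, match="border"):
            kt.mask_markers_3d(vol, [vol.origin], 2.5)
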