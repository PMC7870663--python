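"""Surface tools: Otsu, iso-surfaces, voxelization, SDT, mesh volume, SNR."""

import numpy as np
import pytest
import trimesh

from innerear.core import VoxelVolume
from innerear.phantom import (
    NOISE_SIGMA_SNR4,
    PhantomParams,
    generate_phantom,
    phantom_region_masks,
)
from innerear.surfaces import (
    extract_iso_surface,
    extract_main_surface,
    keep_main_components,
    mesh_volume,
    otsu_threshold,
    segment_bright_structure,
    signed_distance,
    snr,
    voxelize_mesh,
)


def _vol(values, spacing=0.2):
    values = np.asarray(values, dtype=float)
    return VoxelVolume(values, spacing=(spacing,) * 3, origin=(0, 0, 0))


def _binned_between_class_variance(values, nbins=256):
    """Between-class variance of every split of the 256-bin histogram."""
    hist, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    variances = np.zeros(nbins)
    for k in range(1, nbins):
        w0, w1 = hist[:k].sum(), hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        variances[k] = w0 / total * w1 / total * (mu0 - mu1) ** 2
    return variances, centers


class TestOtsu:
    def test_two_valued_threshold_between(self):
        vals = np.full((4, 4, 4), 10.0)
        vals[:2] = 100.0
        thr = otsu_threshold(_vol(vals))
        assert 10.0 < thr < 100.0

    def test_constant_volume_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            otsu_threshold(_vol(np.ones((3, 3, 3))))

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            n0, n1 = rng.integers(200, 2000, size=2)
            sample = np.concatenate([
                rng.normal(rng.uniform(0, 1), rng.uniform(0.05, 0.3), n0),
                rng.normal(rng.uniform(2, 4), rng.uniform(0.05, 0.5), n1),
            ])
            vol = _vol(np.resize(sample, (12, 12, 12)))
            ours = otsu_threshold(vol)
            variances, centers = _binned_between_class_variance(
                vol.values.ravel())
            # our threshold's split must achieve the exhaustive-scan optimum
            # of the binned criterion (threshold value conventions may place
            # it anywhere strictly inside the optimal flat region)
            k_ours = int(np.searchsorted(centers, ours, side="right"))
            assert variances[k_ours] >= variances.max() * (1 - 1e-9)

    def test_phantom_segmentation_dice_at_snr4(self):
        p = PhantomParams(noise_sigma=NOISE_SIGMA_SNR4)
        channels, _ = generate_phantom(p, seed=1, channels=("t2like",),
                                       truth_meshes=False, truth_volumes=False)
        lab = phantom_region_masks(p, regions=("labyrinth",))["labyrinth"]
        _, mask, _ = segment_bright_structure(channels["t2like"])
        a = np.asarray(mask.values).astype(bool)
        b = np.asarray(lab.values).astype(bool)
        dice = 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
        assert dice >= 0.95


def _sphere_image(radius=5.0, spacing=0.2, n=60):
    ax = (np.arange(n) - n / 2 + 0.5) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vals = (np.sqrt(X**2 + Y**2 + Z**2) <= radius).astype(float)
    return VoxelVolume(vals, spacing=(spacing,) * 3, origin=(ax[0],) * 3)


class TestIsoSurface:
    def test_sphere_volume_within_one_percent(self):
        mesh = extract_iso_surface(_sphere_image(), 0.5)
        assert mesh_volume(mesh) == pytest.approx(4 / 3 * np.pi * 125, rel=0.01)

    def test_boundary_touching_level_set_flagged_open(self):
        vals = np.zeros((10, 10, 10))
        vals[:, :, :5] = 1.0  # slab runs out of the grid on four sides
        mesh = extract_iso_surface(_vol(vals), 0.5)
        assert mesh.metadata["open"]

    def test_empty_level_set_rejected(self):
        with pytest.raises(ValueError, match="level"):
            extract_iso_surface(_vol(np.zeros((4, 4, 4)) + 0.2), 5.0)

    def test_phantom_surface_close_to_truth(self, coarse_noiseless,
                                            coarse_labyrinth_mask):
        channels, _ = coarse_noiseless
        mesh = extract_main_surface(channels["t2like"], 0.55)
        sdt = signed_distance(coarse_labyrinth_mask)
        idx = sdt.index_from_world(np.asarray(mesh.vertices))
        from scipy import ndimage
        d = ndimage.map_coordinates(np.asarray(sdt.values, float), idx.T,
                                    order=1)
        assert float(np.abs(d).mean()) < 0.2


class TestComponents:
    def test_speckles_removed(self, coarse_labyrinth_mask, rng):
        from scipy import ndimage as ndi

        mask = np.asarray(coarse_labyrinth_mask.values).astype(bool).copy()
        # sprinkle isolated salt voxels well away from the structure
        dist = ndi.distance_transform_edt(~mask)
        free = np.argwhere(dist > 3)
        for i in rng.choice(len(free), size=50, replace=False):
            mask[tuple(free[i])] = True
        cleaned = keep_main_components(
            coarse_labyrinth_mask.copy(values=mask), k=1)
        np.testing.assert_array_equal(
            cleaned.values.astype(bool),
            np.asarray(coarse_labyrinth_mask.values).astype(bool))

    def test_single_component_unchanged(self):
        vals = np.zeros((8, 8, 8), bool)
        vals[2:5, 2:5, 2:5] = True
        out = keep_main_components(_vol(vals), k=1)
        np.testing.assert_array_equal(out.values.astype(bool), vals)

    def test_tie_break_is_deterministic(self):
        vals = np.zeros((12, 4, 4), bool)
        vals[0:2, 0:2, 0:2] = True
        vals[8:10, 0:2, 0:2] = True  # same size, larger centroid
        out = keep_main_components(_vol(vals), k=1)
        assert out.values[0:2].sum() == 8 and out.values[8:10].sum() == 0

    def test_fewer_components_than_requested_warns(self):
        vals = np.zeros((6, 6, 6), bool)
        vals[1:3, 1:3, 1:3] = True
        with pytest.warns(UserWarning, match="component"):
            keep_main_components(_vol(vals), k=3)


class TestVoxelize:
    def test_unit_cube(self):
        box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        v = voxelize_mesh(box, spacing=0.1)
        assert v.values.sum() * 0.1**3 == pytest.approx(1.0, rel=0.02)

    def test_sphere_2mm(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        v = voxelize_mesh(sphere, spacing=0.1)
        assert v.values.sum() * 0.1**3 == pytest.approx(4.19, rel=0.02)

    def test_roundtrip_with_iso_surface(self):
        img = _sphere_image()
        mesh = extract_iso_surface(img, 0.5)
        vox = voxelize_mesh(mesh, grid=img.copy(
            values=np.zeros(img.shape, dtype=np.uint8)))
        a = vox.values.astype(bool)
        b = img.values > 0.5
        dice = 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
        assert dice >= 0.98

    def test_open_mesh_rejected(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        open_mesh = trimesh.Trimesh(box.vertices, box.faces[:-2], process=False)
        with pytest.raises(ValueError, match="closed"):
            voxelize_mesh(open_mesh, spacing=0.2)


class TestSignedDistance:
    def test_single_interior_voxel(self):
        vals = np.zeros((7, 7, 7), bool)
        vals[3, 3, 3] = True
        sdt = signed_distance(_vol(vals, spacing=0.1))
        assert sdt.values[3, 3, 3] == pytest.approx(-0.1)
        assert sdt.values[4, 3, 3] == pytest.approx(0.1)
        assert sdt.values[4, 4, 3] == pytest.approx(0.1 * np.sqrt(2))
        assert sdt.values[4, 4, 4] == pytest.approx(0.1 * np.sqrt(3))

    def test_half_space_is_linear(self):
        vals = np.zeros((10, 4, 4), bool)
        vals[:5] = True
        sdt = signed_distance(_vol(vals, spacing=0.5))
        expected = 0.5 * np.array([-5, -4, -3, -2, -1, 1, 2, 3, 4, 5])
        np.testing.assert_allclose(sdt.values[:, 2, 2], expected)

    def test_sphere_center_depth(self):
        img = _sphere_image(radius=3.0, spacing=0.2, n=40)
        sdt = signed_distance(img.copy(values=img.values > 0.5))
        center = np.unravel_index(np.argmin(sdt.values), sdt.shape)
        assert abs(sdt.values[center]) == pytest.approx(
            3.0, abs=np.linalg.norm(sdt.spacing))

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(ValueError):
            signed_distance(_vol(np.zeros((4, 4, 4), bool)))
        with pytest.raises(ValueError):
            signed_distance(_vol(np.ones((4, 4, 4), bool)))

    def test_matches_brute_force_nearest_voxel(self, rng):
        """Independent oracle: nearest opposite-class voxel center search."""
        from scipy.spatial import cKDTree

        for _ in range(5):
            vals = rng.random((20, 20, 20)) < 0.2
            if not vals.any() or vals.all():
                continue
            v = _vol(vals, spacing=0.13)
            sdt = signed_distance(v)
            pts = np.argwhere(np.ones_like(vals)) * 0.13
            inside = vals.ravel()
            d_in = cKDTree(np.argwhere(vals) * 0.13).query(pts)[0]
            d_out = cKDTree(np.argwhere(~vals) * 0.13).query(pts)[0]
            expected = np.where(inside, -d_out, d_in).reshape(vals.shape)
            half_diag = 0.5 * np.sqrt(3) * 0.13
            assert np.abs(sdt.values - expected).max() <= half_diag + 1e-9


class TestMeshVolume:
    def test_reference_shapes(self):
        sphere = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        assert mesh_volume(sphere) == pytest.approx(4.2, abs=0.05)
        cube = trimesh.creation.box(extents=(1, 1, 1))
        assert mesh_volume(cube) == pytest.approx(1.0, abs=1e-12)
        cone = trimesh.creation.cone(radius=4.0, height=5.0, sections=256)
        assert mesh_volume(cone) == pytest.approx(83.8, abs=0.05)

    def test_open_mesh_error_names_boundary_edges(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        open_mesh = trimesh.Trimesh(box.vertices, box.faces[:-1], process=False)
        with pytest.raises(ValueError, match=r"\d+ boundary edge"):
            mesh_volume(open_mesh)

    def test_rigid_invariance_and_cubic_scaling(self, rng):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=1.3)
        v0 = mesh_volume(mesh)
        moved = mesh.copy()
        angle = rng.uniform(0, np.pi)
        moved.apply_transform(trimesh.transformations.rotation_matrix(
            angle, rng.normal(size=3), point=rng.normal(size=3)))
        moved.apply_translation(rng.normal(size=3) * 10)
        assert mesh_volume(moved) == pytest.approx(v0, rel=1e-9)
        scaled = mesh.copy()
        scaled.apply_scale(1.7)
        assert mesh_volume(scaled) == pytest.approx(v0 * 1.7**3, rel=1e-9)

    def test_orientation_independent(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        flipped = mesh.copy()
        flipped.invert()
        assert mesh_volume(flipped) == pytest.approx(mesh_volume(mesh))


class TestSnr:
    def test_hand_computed(self):
        vals = np.array([1.0, 1.0, 3.0, 3.0]).reshape(1, 2, 2)
        roi = np.ones((1, 2, 2), bool)
        assert snr(_vol(vals), _vol(roi)) == pytest.approx(2.0)

    def test_constant_roi_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snr(_vol(np.ones((2, 2, 2))), _vol(np.ones((2, 2, 2), bool)))

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            snr(_vol(np.ones((2, 2, 2))), _vol(np.zeros((2, 2, 2), bool)))
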