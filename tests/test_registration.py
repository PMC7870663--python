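"""SDT registration, mesh transfer, label voxelization, scala split."""

import numpy as np
import pytest
import trimesh

from innerear.core import VoxelVolume
from innerear.phantom import (
    PhantomParams,
    generate_phantom,
    phantom_region_masks,
)
from innerear.registration import (
    DeformationField,
    register_sdt,
    split_cochlea_by_threshold,
    transfer_meshes,
    voxelize_labels,
)
from innerear.surfaces import signed_distance
from innerear.validation import dice

COARSE = dict(spacing=0.4, extent_mm=(36.0, 36.0, 28.0))


@pytest.fixture(scope="module")
def coarse_sdt():
    p = PhantomParams(noise_sigma=0.0, **COARSE)
    mask = phantom_region_masks(p, regions=("labyrinth",))["labyrinth"]
    return signed_distance(mask)


def _identity_field(grid, displacement=None):
    disp = (np.zeros(grid.shape + (3,)) if displacement is None
            else displacement)
    return DeformationField(displacement=disp, grid=grid.copy(),
                            affine=np.eye(4))


class TestRegisterSdt:
    def test_self_registration_is_identity(self, coarse_sdt):
        field = register_sdt(coarse_sdt, coarse_sdt, iterations=15)
        assert np.abs(field.displacement).max() < 0.01

    def test_known_translation_recovered(self, coarse_sdt):
        shift = np.array([1.5, 0.0, 0.0])
        moved = coarse_sdt.copy()
        moved.origin = moved.origin + shift
        field = register_sdt(coarse_sdt, moved, iterations=15)
        probe = np.array([[0.0, 0.0, 0.0], [2.0, -1.0, 1.0]])
        recovered = field.apply_points(probe) - probe
        np.testing.assert_allclose(recovered, np.tile(shift, (2, 1)), atol=0.1)

    def test_band_mismatch_strictly_decreases(self):
        pA = PhantomParams(noise_sigma=0.0, global_scale=0.96, **COARSE)
        pB = PhantomParams(noise_sigma=0.0, global_scale=1.05, **COARSE)
        sA = signed_distance(
            phantom_region_masks(pA, regions=("labyrinth",))["labyrinth"])
        sB = signed_distance(
            phantom_region_masks(pB, regions=("labyrinth",))["labyrinth"])
        field = register_sdt(sA, sB, iterations=25)
        h = field.history
        assert h["final"] < h["after_linear"] < h["initial"]
        # narrow-band mismatch decreases across resolution levels
        level_ends = [h[f"demons_level_{level}"][-1] for level in (4, 2, 1)]
        assert level_ends[-1] <= level_ends[0]
        assert field.jacobian_positive_fraction() > 0.99

    def test_rigid_stage_inverse_consistent(self):
        """Swapping fixed and moving must invert the recovered rotation."""
        from scipy.ndimage import rotate

        p = PhantomParams(noise_sigma=0.0, **COARSE)
        mask = phantom_region_masks(p, regions=("labyrinth",))["labyrinth"]
        rotated = mask.copy(values=(rotate(
            mask.values.astype(float), 12.0, axes=(0, 1), reshape=False,
            order=1) > 0.5))
        sA, sB = signed_distance(mask), signed_distance(rotated)
        f_ab = register_sdt(sA, sB, stages=("rigid",))
        f_ba = register_sdt(sB, sA, stages=("rigid",))
        composed = f_ab.affine[:3, :3] @ f_ba.affine[:3, :3]
        angle = np.degrees(np.arccos(
            np.clip((np.trace(composed) - 1) / 2, -1, 1)))
        assert angle < 0.5

    def test_empty_level_set_rejected(self, coarse_sdt):
        flat = coarse_sdt.copy(values=np.abs(coarse_sdt.values) + 1.0)
        with pytest.raises(ValueError, match="zero level"):
            register_sdt(coarse_sdt, flat)
        with pytest.raises(ValueError, match="zero level"):
            register_sdt(flat, coarse_sdt)


class TestTransferMeshes:
    def test_identity_field_leaves_meshes(self, coarse_sdt, default_truth):
        field = _identity_field(coarse_sdt)
        moved = transfer_meshes(default_truth.region_meshes, field)
        for name, mesh in moved.items():
            src = default_truth.region_meshes[name]
            np.testing.assert_allclose(mesh.vertices, src.vertices, atol=1e-12)
            assert len(mesh.faces) == len(src.faces)
            assert mesh.is_watertight

    def test_uniform_translation_shifts_centroids(self, coarse_sdt,
                                                  default_truth):
        disp = np.zeros(coarse_sdt.shape + (3,))
        disp[..., 1] = 1.0
        field = _identity_field(coarse_sdt, disp)
        moved = transfer_meshes(default_truth.region_meshes, field)
        for name, mesh in moved.items():
            src = default_truth.region_meshes[name].vertices.mean(axis=0)
            shift = mesh.vertices.mean(axis=0) - src
            np.testing.assert_allclose(shift, [0.0, 1.0, 0.0], atol=1e-9)

    def test_vertices_outside_grid_counted(self, coarse_sdt):
        field = _identity_field(coarse_sdt)
        far = trimesh.creation.icosphere(subdivisions=1, radius=1.0)
        far.apply_translation([500.0, 0.0, 0.0])
        with pytest.raises(ValueError, match=r"\d+ point"):
            transfer_meshes({"far": far}, field)


class TestVoxelizeLabels:
    def test_disjoint_spheres_counts(self):
        a = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        b = trimesh.creation.icosphere(subdivisions=4, radius=1.2)
        b.apply_translation([4.0, 0.0, 0.0])
        lm = voxelize_labels({"saccule": a, "utricle": b}, spacing=0.1)
        voxel = lm.volume.voxel_volume
        counts = {name: (lm.volume.values == lab).sum() * voxel
                  for lab, name in lm.names.items()}
        assert counts["saccule"] == pytest.approx(4 / 3 * np.pi, rel=0.02)
        assert counts["utricle"] == pytest.approx(4 / 3 * np.pi * 1.2**3,
                                                  rel=0.02)

    def test_nested_meshes_inner_label_wins(self):
        outer = trimesh.creation.icosphere(subdivisions=3, radius=1.5)
        inner = trimesh.creation.icosphere(subdivisions=3, radius=0.6)
        # cochlear_duct precedes scala_vestibuli in the precedence order
        lm = voxelize_labels(
            {"scala_vestibuli": outer, "cochlear_duct": inner}, spacing=0.1)
        duct_label = [k for k, v in lm.names.items() if v == "cochlear_duct"][0]
        count = (lm.volume.values == duct_label).sum() * lm.volume.voxel_volume
        assert count == pytest.approx(4 / 3 * np.pi * 0.6**3, rel=0.03)

    def test_phantom_regions_against_truth_masks(self, default_truth):
        # voxelized meshes vs analytically rasterized masks, same 0.2 mm grid
        p = PhantomParams()
        masks = phantom_region_masks(p, regions=("ampulla_lat", "saccule",
                                                 "common_crus"))
        grid = masks["saccule"]
        lm = voxelize_labels(
            {k: default_truth.region_meshes[k] for k in masks},
            grid=grid.copy(values=np.zeros(grid.shape, dtype=np.int16)))
        for lab, name in lm.names.items():
            d = dice(lm.volume.copy(values=lm.volume.values == lab),
                     masks[name])
            assert d >= 0.85, name


@pytest.fixture(scope="module")
def ciss_setup():
    p = PhantomParams(noise_sigma=0.0)
    channels, _ = generate_phantom(p, seed=2, channels=("cisslike",),
                                   truth_meshes=False, truth_volumes=False)
    masks = phantom_region_masks(
        p, regions=("cochlea", "scala_vestibuli", "scala_tympani"))
    return channels["cisslike"], masks


class TestSplitCochlea:
    def test_scalae_recovered(self, ciss_setup):
        ciss, masks = ciss_setup
        lm = split_cochlea_by_threshold(ciss, masks["cochlea"], threshold=0.45)
        assert set(lm.names.values()) == {"scala_vestibuli", "scala_tympani"}
        for lab, name in lm.names.items():
            d = dice(lm.volume.copy(values=lm.volume.values == lab),
                     masks[name])
            assert d >= 0.8, name

    def test_threshold_below_background_rejected(self, ciss_setup):
        ciss, masks = ciss_setup
        with pytest.raises(ValueError, match="separation"):
            split_cochlea_by_threshold(ciss, masks["cochlea"], threshold=-1.0)

    def test_degenerate_gap_yields_single_component(self):
        p = PhantomParams(noise_sigma=0.0, scala_gap=1e-3, **COARSE)
        channels, _ = generate_phantom(p, seed=0, channels=("cisslike",),
                                       truth_meshes=False, truth_volumes=False)
        mask = phantom_region_masks(p, regions=("cochlea",))["cochlea"]
        with pytest.raises(ValueError, match="component"):
            split_cochlea_by_threshold(channels["cisslike"], mask,
                                       threshold=0.45)
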