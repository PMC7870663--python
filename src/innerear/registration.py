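"""Surface-driven registration and atlas label transfer.

The atlas annotation strategy: the reference (atlas) labyrinth surface and
the target surface are converted into signed-distance-transform (SDT)
volumes, which serve as surrogate images for intensity-based registration.
A rigid + affine stage (moments-initialized least squares on the truncated
SDTs) is followed by a diffusion-regularized demons-style deformable stage,
yielding a
map from atlas space into subject/template space.  Region meshes are pushed
through that map and voxelized into a labelmap with a deterministic
precedence order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage

from .core import SegmentationLabelmap, VoxelVolume
from .surfaces import voxelize_mesh

__all__ = [
    "DeformationField",
    "RegistrationError",
    "register_sdt",
    "transfer_meshes",
    "voxelize_labels",
    "split_cochlea_by_threshold",
    "warp_volume",
    "LABEL_PRECEDENCE",
]

#: precedence when voxelized regions overlap: earlier wins, so thin
#: structures are not swallowed by the large chambers around them
LABEL_PRECEDENCE = (
    "ampulla_ant", "ampulla_post", "ampulla_lat",
    "common_crus",
    "scc_ant", "scc_post", "scc_lat",
    "cochlear_duct", "cupula",
    "scala_vestibuli", "scala_tympani",
    "saccule", "utricle", "vestibule",
)

_NARROW_BAND_MM = 1.0  # convergence is judged near the surface only


class RegistrationError(RuntimeError):
    pass


@dataclass
class DeformationField:
    """Total map ``T(x) = x + displacement(x)`` from fixed (atlas) space into
    moving (subject) space, sampled on the fixed grid.

    ``affine`` is the linear part (also folded into ``displacement``), kept
    for inspection; ``history`` records the narrow-band mean |SDT mismatch|
    per stage and resolution level.
    """

    displacement: np.ndarray  # (nx, ny, nz, 3) in mm
    grid: VoxelVolume
    affine: np.ndarray
    history: dict = field(default_factory=dict)

    def apply_points(self, pts: np.ndarray, strict: bool = True) -> np.ndarray:
        """Map points (mm, fixed space) through the deformation."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        idx = self.grid.index_from_world(pts)
        shape = np.asarray(self.grid.shape)
        outside = np.any((idx < 0) | (idx > shape - 1), axis=1)
        if outside.any() and strict:
            raise ValueError(
                f"{int(outside.sum())} point(s) fall outside the deformation grid"
            )
        disp = np.stack(
            [
                ndimage.map_coordinates(self.displacement[..., c], idx.T,
                                        order=1, mode="nearest")
                for c in range(3)
            ],
            axis=1,
        )
        return pts + disp

    def jacobian_positive_fraction(self, mask: np.ndarray | None = None) -> float:
        """Fraction of voxels with positive deformation Jacobian (fold check)."""
        sp = self.grid.spacing
        grads = np.empty(self.grid.shape + (3, 3))
        for c in range(3):
            for d in range(3):
                grads[..., c, d] = np.gradient(
                    self.displacement[..., c], sp[d], axis=d)
        jac = np.eye(3) + grads
        det = np.linalg.det(jac)
        if mask is not None:
            det = det[mask]
        return float(np.mean(det > 0))


def _mask_moments(sdt: VoxelVolume):
    """Centroid (mm) and volume (mm^3) of the SDT's interior (negative) set."""
    inside = np.asarray(sdt.values) < 0
    idx = np.argwhere(inside)
    centroid = sdt.world_from_index(idx.mean(axis=0))
    return centroid, inside.sum() * sdt.voxel_volume


def _interp_world(volume: VoxelVolume, pts: np.ndarray, fill: float):
    idx = volume.index_from_world(pts)
    return ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float), idx.T, order=1,
        mode="constant", cval=fill)


def _linear_stage(fixed: VoxelVolume, moving: VoxelVolume, stages,
                  max_points: int = 40_000) -> np.ndarray:
    """Rigid (and optionally affine) alignment of the SDT surrogates.

    Moments initialization (interior centroids; cube-root volume ratio for
    the affine scale) followed by damped least squares on the mean squared
    SDT difference, evaluated on a subsample of the fixed narrow band.
    Returns the 4x4 matrix mapping fixed physical points into moving space.
    """
    from scipy.optimize import least_squares
    from scipy.spatial.transform import Rotation

    f_vals = np.asarray(fixed.values, dtype=float)
    band_idx = np.argwhere(np.abs(f_vals) < _NARROW_BAND_MM * 2.0)
    if len(band_idx) > max_points:
        step = len(band_idx) // max_points + 1
        band_idx = band_idx[::step]
    pts = fixed.world_from_index(band_idx.astype(float))
    target = f_vals[tuple(band_idx.T)]
    fill = float(np.max(moving.values))
    c_fixed, v_fixed = _mask_moments(fixed)
    c_moving, v_moving = _mask_moments(moving)

    def rigid_matrix(p):
        mat = np.eye(4)
        mat[:3, :3] = Rotation.from_rotvec(p[:3]).as_matrix()
        mat[:3, 3] = p[3:6] + c_moving - mat[:3, :3] @ c_fixed
        return mat

    def residual_for(matrix_fn):
        def residual(p):
            mat = matrix_fn(p)
            mapped = pts @ mat[:3, :3].T + mat[:3, 3]
            # a map that scales space by s also scales SDT values by s; the
            # geometrically exact map must be a zero of the residual
            s = abs(float(np.linalg.det(mat[:3, :3]))) ** (1.0 / 3.0)
            return _interp_world(moving, mapped, fill) - s * target
        return residual

    matrix = rigid_matrix(np.zeros(6))
    if "rigid" in stages:
        sol = least_squares(residual_for(rigid_matrix), np.zeros(6),
                            method="lm", max_nfev=400)
        matrix = rigid_matrix(sol.x)
    if "affine" in stages:
        scale0 = (v_moving / v_fixed) ** (1.0 / 3.0)

        def affine_matrix(p):
            mat = np.eye(4)
            mat[:3, :3] = p[:9].reshape(3, 3)
            mat[:3, 3] = p[9:12]
            return mat

        lin0 = matrix[:3, :3] * scale0
        p0 = np.concatenate([
            lin0.ravel(),
            c_moving - lin0 @ c_fixed + (matrix[:3, 3]
                                         - (c_moving - matrix[:3, :3] @ c_fixed)),
        ])
        sol = least_squares(residual_for(affine_matrix), p0,
                            method="lm", max_nfev=600)
        matrix = affine_matrix(sol.x)
    return matrix


def _sample(values: np.ndarray, idx: np.ndarray, fill: float) -> np.ndarray:
    return ndimage.map_coordinates(values, idx, order=1, mode="constant",
                                   cval=fill)


def _apply_affine_grid(moving: VoxelVolume, fixed: VoxelVolume,
                       matrix: np.ndarray) -> np.ndarray:
    """Resample moving onto the fixed grid through the affine map."""
    idx = np.indices(fixed.shape, dtype=float)
    world = fixed.world_from_index(np.moveaxis(idx, 0, -1))
    mapped = world @ matrix[:3, :3].T + matrix[:3, 3]
    src = moving.index_from_world(mapped)
    fill = float(np.max(moving.values))
    return _sample(np.asarray(moving.values, dtype=float),
                   np.moveaxis(src, -1, 0), fill)


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    return ndimage.zoom(arr, 1.0 / factor, order=1, grid_mode=True,
                        mode="nearest")


def _demons(fixed: np.ndarray, moving: np.ndarray, spacing: np.ndarray,
            levels=(4, 2, 1), iterations: int = 50, sigma_field_vox: float = 1.0,
            history: dict | None = None) -> np.ndarray:
    """Diffusion-regularized demons on SDT volumes.

    Per-voxel update ``u = -(m - f) grad m / (|grad m|^2 + (m - f)^2)``,
    followed by Gaussian smoothing of the accumulated displacement field
    (sigma = 1 voxel by default).  Multi-resolution coarse-to-fine; the
    narrow-band (|SDT| < 1 mm) mean absolute mismatch is recorded per level.
    """
    disp = None  # (3, ...) mm, on the current level grid
    for level in levels:
        f = _downsample(fixed, level)
        m = _downsample(moving, level)
        sp = spacing * level
        if disp is None:
            disp = np.zeros((3,) + f.shape)
        else:
            disp = np.stack([
                ndimage.zoom(disp[c], np.asarray(f.shape) / disp[c].shape,
                             order=1, mode="nearest")
                for c in range(3)
            ])
        idx0 = np.indices(f.shape, dtype=float)
        band = np.abs(f) < _NARROW_BAND_MM
        if not band.any():
            band = np.abs(f) < 2.0 * _NARROW_BAND_MM
        metrics = []
        fill = float(m.max())
        for _ in range(iterations):
            idx = idx0 + disp / sp[:, None, None, None]
            warped = _sample(m, idx, fill)
            diff = warped - f
            metrics.append(float(np.mean(np.abs(diff[band]))))
            grads = np.stack(np.gradient(warped, *sp))
            denom = np.sum(grads**2, axis=0) + diff**2
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(denom > 1e-9, -diff / denom, 0.0)
            update = step[None] * grads
            # cap the per-iteration step at half a voxel for stability
            mag = np.sqrt(np.sum(update**2, axis=0))
            cap = 0.5 * float(sp.min())
            scale = np.where(mag > cap, cap / np.maximum(mag, 1e-12), 1.0)
            disp = disp + update * scale[None]
            disp = np.stack([
                ndimage.gaussian_filter(disp[c], sigma_field_vox)
                for c in range(3)
            ])
        idx = idx0 + disp / sp[:, None, None, None]
        metrics.append(float(np.mean(np.abs(_sample(m, idx, fill)[band] - f[band]))))
        if history is not None:
            history[f"demons_level_{level}"] = metrics
    return np.moveaxis(disp, 0, -1)


def register_sdt(fixed: VoxelVolume, moving: VoxelVolume,
                 stages=("rigid", "affine", "deformable"),
                 iterations: int = 50, sigma_field_vox: float = 1.0,
                 levels=(4, 2, 1), clamp_mm: float = 2.0) -> DeformationField:
    """Register two signed-distance volumes; returns the fixed->moving map.

    Multi-resolution mean-squared-SDT-difference minimization:
    rigid -> affine (SimpleITK) -> demons-style deformable (in-house).
    Both SDTs are truncated at ``+-clamp_mm`` first: far from the surface the
    distance values of two differently sized shapes disagree even under the
    geometrically correct map, and untruncated far fields bias the linear
    stage.  To transfer atlas annotations onto a subject, pass the *atlas*
    SDT as ``fixed`` and the subject SDT as ``moving``: the resulting map
    carries atlas-space points (e.g. mesh vertices) into subject space.
    """
    if not np.allclose(fixed.spacing, moving.spacing):
        raise ValueError("fixed and moving SDTs must share a voxel spacing")
    for name, sdt in (("fixed", fixed), ("moving", moving)):
        vals = np.asarray(sdt.values)
        if vals.min() > 0 or vals.max() < 0:
            raise ValueError(f"{name} SDT has an empty zero level set")
    history: dict = {}
    fixed = fixed.copy(values=np.clip(fixed.values, -clamp_mm, clamp_mm))
    moving = moving.copy(values=np.clip(moving.values, -clamp_mm, clamp_mm))
    f = np.asarray(fixed.values, dtype=float)
    band = np.abs(f) < _NARROW_BAND_MM
    matrix = np.eye(4)
    history["initial"] = float(np.mean(np.abs(
        _apply_affine_grid(moving, fixed, np.eye(4))[band] - f[band])))
    if "rigid" in stages or "affine" in stages:
        matrix = _linear_stage(fixed, moving, stages)
    # normalize the warped SDT values by the volume-change factor so that the
    # deformable stage sees consistent distance units
    scale_factor = abs(float(np.linalg.det(matrix[:3, :3]))) ** (1.0 / 3.0)
    moving_lin = _apply_affine_grid(moving, fixed, matrix) / scale_factor
    history["after_linear"] = float(np.mean(np.abs(moving_lin[band] - f[band])))
    if history["after_linear"] >= history["initial"] * (1.0 - 1e-9):
        # the optimizer found nothing better than where it started (e.g. the
        # inputs already coincide); keep the identity
        matrix = np.eye(4)
        moving_lin = _apply_affine_grid(moving, fixed, matrix)
        history["after_linear"] = history["initial"]
    if np.min(np.abs(moving_lin[band])) > 5.0:
        raise RegistrationError(
            "zero level sets do not overlap after linear alignment; "
            "registration diverged"
        )
    if "deformable" in stages:
        disp_demons = _demons(f, moving_lin, fixed.spacing, levels=levels,
                              iterations=iterations,
                              sigma_field_vox=sigma_field_vox,
                              history=history)
    else:
        disp_demons = np.zeros(fixed.shape + (3,))
    # total map: T(x) = A(x + d(x))
    idx = np.indices(fixed.shape, dtype=float)
    world = fixed.world_from_index(np.moveaxis(idx, 0, -1))
    bent = world + disp_demons
    total = bent @ matrix[:3, :3].T + matrix[:3, 3]
    displacement = total - world
    final_idx = np.moveaxis(moving.index_from_world(total), -1, 0)
    history["final"] = float(np.mean(np.abs(
        _sample(np.asarray(moving.values, dtype=float), final_idx,
                float(np.max(moving.values)))[band] - f[band])))
    return DeformationField(displacement=displacement, grid=fixed.copy(),
                            affine=matrix, history=history)


def warp_volume(moving: VoxelVolume, deformation: DeformationField,
                order: int = 1, fill: float | None = None) -> VoxelVolume:
    """Pull the moving volume back onto the deformation's (fixed) grid."""
    grid = deformation.grid
    idx = np.indices(grid.shape, dtype=float)
    world = grid.world_from_index(np.moveaxis(idx, 0, -1))
    target = world + deformation.displacement
    src = moving.index_from_world(target)
    fill = float(np.median(moving.values)) if fill is None else fill
    out = ndimage.map_coordinates(np.asarray(moving.values, dtype=float),
                                  np.moveaxis(src, -1, 0), order=order,
                                  mode="constant", cval=fill)
    return grid.copy(values=out)


def transfer_meshes(regions: dict[str, trimesh.Trimesh],
                    deformation: DeformationField
                    ) -> dict[str, trimesh.Trimesh]:
    """Push region meshes through the deformation (trilinear displacement
    interpolation at the vertices; faces unchanged, closedness preserved)."""
    out = {}
    for name, mesh in regions.items():
        moved = deformation.apply_points(np.asarray(mesh.vertices))
        warped = trimesh.Trimesh(vertices=moved, faces=mesh.faces.copy(),
                                 process=False)
        out[name] = warped
    return out


def voxelize_labels(regions: dict[str, trimesh.Trimesh],
                    spacing: float = 0.2,
                    grid: VoxelVolume | None = None) -> SegmentationLabelmap:
    """Voxelize closed region meshes into one labelmap.

    Overlap between regions is resolved by :data:`LABEL_PRECEDENCE` (earlier
    entries win); regions not listed there are appended after, in input
    order.  Nested meshes therefore keep the smaller/thinner structure.
    """
    order = [r for r in LABEL_PRECEDENCE if r in regions]
    order += [r for r in regions if r not in order]
    if grid is None:
        bounds = np.array([m.bounds for m in regions.values()])
        lo = bounds[:, 0, :].min(axis=0) - spacing
        hi = bounds[:, 1, :].max(axis=0) + spacing
        shape = np.ceil((hi - lo) / spacing).astype(int) + 1
        grid = VoxelVolume(values=np.zeros(tuple(shape), dtype=np.int16),
                           spacing=np.full(3, spacing), origin=lo)
    labels = np.zeros(grid.shape, dtype=np.int16)
    names: dict[int, str] = {}
    for label, name in enumerate(order, start=1):
        mask = voxelize_mesh(regions[name], grid=grid).values.astype(bool)
        labels[mask & (labels == 0)] = label
        names[label] = name
    return SegmentationLabelmap(volume=grid.copy(values=labels), names=names)


def split_cochlea_by_threshold(ciss: VoxelVolume, cochlea_mask: VoxelVolume,
                               threshold: float, closing_radius: int = 1,
                               min_seed_fraction: float = 0.2
                               ) -> SegmentationLabelmap:
    """Split the cochlea into scala vestibuli / scala tympani.

    Voxels of the cochlea mask brighter than ``threshold`` are grouped into
    connected components; the two largest become the scalae (the superior
    one, by world-z centroid, is labelled scala vestibuli).  Smaller
    components are merged into the nearest scala, and a morphological
    closing (radius 1 voxel by default) substitutes for the manual cleanup
    of a human annotator.
    """
    mask = np.asarray(cochlea_mask.values).astype(bool)
    if not mask.any():
        raise ValueError("empty cochlea mask")
    bright = (np.asarray(ciss.values) > threshold) & mask
    if bright.sum() > 0.95 * mask.sum():
        raise ValueError(
            "threshold below the dark inter-scalae gap: no separation "
            "obtained; raise the threshold"
        )
    # seeds come from an eroded copy: the inter-scalae gap is a sheet only
    # about a voxel thick, and partial-volume pinholes would otherwise bridge
    # the two scalae; 6-connectivity for the same reason
    eroded = ndimage.binary_erosion(bright)
    labels, n = ndimage.label(eroded)
    if n < 2:
        raise ValueError(
            f"only {n} bright component(s) inside the cochlea; adjust the "
            "threshold to separate the scalae"
        )
    sizes = ndimage.sum_labels(eroded, labels, index=np.arange(1, n + 1))
    top2 = np.argsort(sizes)[::-1][:2] + 1
    if sizes[top2[1] - 1] < min_seed_fraction * sizes[top2[0] - 1]:
        # a vanishing gap leaves one bright snake plus erosion crumbs, not
        # two comparably sized scalae
        raise ValueError(
            "second bright component is only "
            f"{sizes[top2[1] - 1] / sizes[top2[0] - 1]:.0%} of the largest; "
            "no scala separation at this threshold"
        )
    zc = []
    for lab in top2:
        com = ndimage.center_of_mass(labels == lab)
        zc.append(ciss.world_from_index(np.asarray(com))[2])
    sup, inf = (top2[0], top2[1]) if zc[0] >= zc[1] else (top2[1], top2[0])
    two = np.zeros_like(labels)
    two[labels == sup] = 1
    two[labels == inf] = 2
    # every remaining bright voxel (incl. smaller components) joins the
    # nearest scala seed
    _, (ix, iy, iz) = ndimage.distance_transform_edt(
        two == 0, sampling=tuple(ciss.spacing), return_indices=True)
    filled = two[ix, iy, iz]
    out = np.where(bright, np.where(two > 0, two, filled), 0)
    if closing_radius > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        structure = ndimage.iterate_structure(structure, closing_radius)
        for lab in (1, 2):
            closed = ndimage.binary_closing(out == lab, structure=structure)
            out[closed & (out == 0) & mask] = lab
    return SegmentationLabelmap(
        volume=ciss.copy(values=out.astype(np.int16)),
        names={1: "scala_vestibuli", 2: "scala_tympani"},
    )
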