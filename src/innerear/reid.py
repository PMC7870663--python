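"""Reid's standard plane: fitting, reorientation, ROI cropping, mirroring.

Reid's plane is the axial anatomical reference plane through the two
infraorbital points and the two external auditory meati.  Volumes are
reoriented so that this plane becomes the grid's axial plane, which also
brings the lateral semicircular canal approximately into the axial plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LandmarkSet, VoxelVolume
from .phantom import REID_LANDMARK_NAMES

__all__ = [
    "PlaneFit",
    "RoiSpec",
    "fit_plane",
    "fit_reid_plane",
    "rotation_to_plane",
    "reorient_to_plane",
    "reorient_landmarks",
    "crop_roi",
    "mirror_sagittal",
]


@dataclass
class PlaneFit:
    """Total-least-squares plane: unit normal, a point on the plane, and the
    root-mean-square perpendicular residual (mm)."""

    normal: np.ndarray
    point: np.ndarray
    residual: float

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        self.point = np.asarray(self.point, dtype=float).reshape(3)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0):
            self.normal = self.normal / n

    def distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(pts) - self.point) @ self.normal


@dataclass
class RoiSpec:
    """Inner-ear region of interest: a 4 x 4 x 3 cm box at 0.2 mm."""

    center: np.ndarray
    extents: tuple[float, float, float] = (40.0, 40.0, 30.0)
    spacing: float = 0.2

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if any(e <= 0 for e in self.extents) or self.spacing <= 0:
            raise ValueError("ROI extents and spacing must be positive")


class DegenerateFitError(ValueError):
    """Raised when the landmark configuration cannot define a plane."""


def fit_plane(points: np.ndarray) -> PlaneFit:
    """Orientation-free (total least squares) plane through >= 3 points.

    Minimizes the sum of squared perpendicular distances; the solution is the
    smallest right singular vector of the centered coordinate matrix.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 3 or points.shape[1] != 3:
        raise DegenerateFitError("need at least 3 points in 3-D")
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear (or coincident) points: the second singular value vanishes
    scale = max(svals[0], 1e-30)
    if svals[1] / scale < 1e-9:
        raise DegenerateFitError("points are collinear; plane is undefined")
    normal = vt[2]
    residual = float(np.sqrt(np.mean(((centered @ normal) ** 2))))
    return PlaneFit(normal=normal, point=centroid, residual=residual)


def fit_reid_plane(landmarks: LandmarkSet) -> PlaneFit:
    """Fit Reid's plane from the four named head landmarks.

    Requires exactly the landmarks ``infraorbital_left/right`` and
    ``auditory_meatus_left/right`` to be present; the normal is returned
    pointing superior (positive z component).
    """
    missing = [n for n in REID_LANDMARK_NAMES if n not in landmarks]
    if missing:
        raise KeyError(f"missing Reid landmarks: {missing}")
    pts = landmarks.as_array(REID_LANDMARK_NAMES)
    if len(np.unique(pts.round(9), axis=0)) < 4:
        raise DegenerateFitError("duplicate Reid landmarks")
    fit = fit_plane(pts)
    if fit.normal[2] < 0:
        fit.normal = -fit.normal
    return fit


def rotation_to_plane(plane: PlaneFit) -> np.ndarray:
    """Smallest rotation matrix taking the plane normal to the superior axis.

    The in-plane orientation is not constrained by the plane itself; the
    minimal-angle rotation about ``normal x z`` is the stated convention.
    """
    n = plane.normal if plane.normal[2] >= 0 else -plane.normal
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(n, z)
    s = np.linalg.norm(v)
    c = float(n @ z)
    if s < 1e-12:
        return np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _volume_center(volume: VoxelVolume) -> np.ndarray:
    return volume.world_from_index((np.asarray(volume.shape) - 1) / 2.0)


def reorient_to_plane(volume: VoxelVolume, plane: PlaneFit,
                      interpolation_order: int = 3) -> VoxelVolume:
    """Rigidly rotate the volume contents so the plane becomes axial.

    The rotation is about the grid center (no scaling or shearing);
    intensities are interpolated with cubic B-splines by default.
    """
    rot = rotation_to_plane(plane)
    center = _volume_center(volume)
    # output voxel at world x samples input at center + R^T (x - center)
    shape = volume.shape
    idx = np.indices(shape, dtype=float)
    world = volume.world_from_index(np.moveaxis(idx, 0, -1))
    src_world = (world - center) @ rot + center  # (x-c) @ R == R^T (x-c)
    src_idx = volume.index_from_world(src_world)
    out = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float),
        np.moveaxis(src_idx, -1, 0),
        order=interpolation_order,
        mode="nearest",
    )
    return volume.copy(values=out)


def reorient_landmarks(landmarks: LandmarkSet, plane: PlaneFit,
                       volume: VoxelVolume) -> LandmarkSet:
    """Apply the same rigid reorientation to a landmark set."""
    rot = rotation_to_plane(plane)
    center = _volume_center(volume)
    return landmarks.transformed(lambda pts: (pts - center) @ rot.T + center)


def _modal_background(values: np.ndarray, bins: int = 256) -> float:
    vals = np.asarray(values, dtype=float).ravel()
    hist, edges = np.histogram(vals, bins=bins)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def crop_roi(volume: VoxelVolume, roi: RoiSpec,
             interpolation_order: int = 3) -> VoxelVolume:
    """Crop and resample the ROI box around ``roi.center``.

    The output grid is ``extents / spacing`` voxels (200 x 200 x 150 for the
    default box); voxels falling outside the input volume are filled with the
    modal background intensity of the input.  Raises if the ROI does not
    intersect the volume at all.
    """
    shape = np.round(np.asarray(roi.extents) / roi.spacing).astype(int)
    spacing = np.full(3, roi.spacing)
    origin = roi.center - (shape - 1) * spacing / 2.0
    out_grid = VoxelVolume(values=np.zeros(shape, dtype=np.float32),
                           spacing=spacing, origin=origin, axes=volume.axes)
    idx = np.indices(tuple(shape), dtype=float)
    world = out_grid.world_from_index(np.moveaxis(idx, 0, -1))
    src_idx = volume.index_from_world(world)
    in_bounds = np.all(
        (src_idx >= 0) & (src_idx <= np.asarray(volume.shape) - 1), axis=-1
    )
    if not in_bounds.any():
        raise ValueError("ROI lies entirely outside the volume")
    fill = _modal_background(volume.values)
    out = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float),
        np.moveaxis(src_idx, -1, 0),
        order=interpolation_order,
        mode="constant",
        cval=fill,
    )
    out[~in_bounds] = fill
    return out_grid.copy(values=out)


def mirror_sagittal(volume: VoxelVolume) -> VoxelVolume:
    """Reflect across the grid's mid-sagittal plane (first grid axis).

    The reflection is an exact involution: applying it twice returns a
    bit-identical volume.  Crops are centered on the anatomy, so mirroring
    about the grid plane (rather than a fitted anatomical midplane) matches
    left ears onto the right-ear orientation.
    """
    return volume.copy(values=volume.values[::-1, :, :].copy())
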