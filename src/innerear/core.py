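"""Core data carriers and file I/O shared by every stage of the pipeline.

Conventions (used consistently across all modules):

* World frame is RAS, in millimetres.
* Voxel indices are 0-based and refer to voxel *centers*:
  ``world = origin + axes @ (index * spacing)``.
* Signed distances are negative inside a structure.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "LandmarkSet",
    "SegmentationLabelmap",
    "FormatError",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "read_mesh",
    "write_mesh",
    "resample",
    "read_cohort_table",
    "write_cohort_table",
    "validate_cohort_table",
]

_ORTHO_TOL = 1e-5


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


# ---------------------------------------------------------------------------
# VoxelVolume
# ---------------------------------------------------------------------------


@dataclass
class VoxelVolume:
    """A 3-D scalar grid with physical geometry.

    Parameters
    ----------
    values
        3-D array of voxel values, indexed ``[i, j, k]``.
    spacing
        Voxel edge lengths in mm, one per axis.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    axes
        Orthonormal direction matrix; column ``d`` is the world direction of
        grid axis ``d``. Identity means grid axes == world axes (RAS).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got shape {self.values.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not _is_orthonormal(self.axes):
            raise ValueError("axes matrix is not orthonormal")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world_from_index(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm coordinates."""
        index = np.asarray(index, dtype=float)
        return self.origin + (index * self.spacing) @ self.axes.T

    def index_from_world(self, world: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional voxel indices."""
        world = np.asarray(world, dtype=float)
        return ((world - self.origin) @ self.axes) / self.spacing

    def grid_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of all voxel centers as three broadcastable axes.

        Only valid for identity ``axes`` (the common case in this package);
        callers needing rotated grids should go through :meth:`world_from_index`.
        """
        if not np.allclose(self.axes, np.eye(3)):
            raise ValueError("grid_coordinates requires identity axes")
        ax = [
            self.origin[d] + np.arange(self.shape[d]) * self.spacing[d]
            for d in range(3)
        ]
        return (
            ax[0][:, None, None],
            ax[1][None, :, None],
            ax[2][None, None, :],
        )

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world affine (voxel centers)."""
        A = np.eye(4)
        A[:3, :3] = self.axes * self.spacing[None, :]
        A[:3, 3] = self.origin
        return A

    def copy(self, values: np.ndarray | None = None) -> "VoxelVolume":
        return replace(
            self, values=self.values.copy() if values is None else values
        )

    def same_grid(self, other: "VoxelVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.axes, other.axes, atol=tol)
        )


def _is_orthonormal(m: np.ndarray, tol: float = _ORTHO_TOL) -> bool:
    return bool(
        np.allclose(m @ m.T, np.eye(3), atol=tol)
        and abs(abs(np.linalg.det(m)) - 1.0) < tol
    )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI-1 volume.

    The qform is preferred and the sform used as a fallback; the direction
    matrix must be orthonormal (no shear), otherwise a :class:`FormatError`
    is raised naming the offending field.
    """
    img = nib.load(str(path))
    affine = img.get_qform() if img.header["qform_code"] > 0 else img.get_sform()
    if affine is None or not np.any(affine[:3, :3]):
        raise FormatError(f"{path}: neither qform nor sform defines a geometry")
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0):
        raise FormatError(f"{path}: non-positive spacing in affine {spacing}")
    axes = linear / spacing[None, :]
    if not _is_orthonormal(axes):
        raise FormatError(
            f"{path}: direction matrix is not orthonormal (shear in affine)"
        )
    values = np.asanyarray(img.dataobj)
    if values.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {values.shape}")
    return VoxelVolume(values=values, spacing=spacing, origin=affine[:3, 3], axes=axes)


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a NIfTI-1 volume; qform and sform are set identically."""
    img = nib.Nifti1Image(np.asarray(volume.values), volume.affine)
    img.set_qform(volume.affine, code=1)
    img.set_sform(volume.affine, code=1)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Landmarks (3D Slicer fiducial CSV dialect)
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    """Named 3-D points (mm) in a stated frame (``subject`` or ``template``)."""

    points: dict[str, np.ndarray]
    frame: str = "subject"

    def __post_init__(self) -> None:
        self.points = {
            str(k): np.asarray(v, dtype=float).reshape(3)
            for k, v in self.points.items()
        }

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def __len__(self) -> int:
        return len(self.points)

    def names(self) -> list[str]:
        return list(self.points)

    def subset(self, names) -> "LandmarkSet":
        return LandmarkSet(
            {n: self.points[n] for n in names if n in self.points}, frame=self.frame
        )

    def as_array(self, names=None) -> np.ndarray:
        names = self.names() if names is None else names
        return np.stack([self.points[n] for n in names])

    def transformed(self, func) -> "LandmarkSet":
        """Apply ``func`` (an (n,3)->(n,3) map) to every point."""
        names = self.names()
        moved = func(self.as_array(names))
        return LandmarkSet(dict(zip(names, moved)), frame=self.frame)


_FCSV_HEADER = "# Markups fiducial file version = 4.11"
_FCSV_COLUMNS = (
    "id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID"
)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    """Write landmarks in the 3D Slicer fiducial CSV (``.fcsv``) dialect."""
    with open(path, "w", newline="") as fh:
        fh.write(_FCSV_HEADER + "\n")
        fh.write("# CoordinateSystem = RAS\n")
        fh.write(f"# columns = {_FCSV_COLUMNS}\n")
        writer = csv.writer(fh)
        for i, (name, p) in enumerate(landmarks.points.items()):
            writer.writerow(
                [f"vtkMRMLMarkupsFiducialNode_{i}",
                 format(float(p[0]), ".17g"), format(float(p[1]), ".17g"),
                 format(float(p[2]), ".17g"),
                 0, 0, 0, 1, 1, 1, 0, name, "", ""]
            )


def read_landmarks(path: str | Path, frame: str = "subject") -> LandmarkSet:
    """Read a Slicer fiducial CSV; unknown columns are ignored with a warning.

    Duplicate landmark names raise a :class:`FormatError`.
    """
    points: dict[str, np.ndarray] = {}
    n_cols_expected = len(_FCSV_COLUMNS.split(","))
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.startswith("# Markups fiducial file"):
            raise FormatError(f"{path}: missing Slicer fiducial file header")
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 12:
                raise FormatError(f"{path}: fiducial row has too few columns: {row}")
            if len(row) > n_cols_expected:
                warnings.warn(
                    f"{path}: ignoring {len(row) - n_cols_expected} unknown "
                    "trailing column(s)", stacklevel=2,
                )
            name = row[11]
            if name in points:
                raise FormatError(f"{path}: duplicate landmark name {name!r}")
            points[name] = np.array([float(row[1]), float(row[2]), float(row[3])])
    return LandmarkSet(points, frame=frame)


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh", process=False)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path}: no triangle mesh found")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path: str | Path) -> None:
    mesh.export(str(path))


# ---------------------------------------------------------------------------
# Segmentation labelmaps
# ---------------------------------------------------------------------------


@dataclass
class SegmentationLabelmap:
    """Integer labelmap plus label -> region-name table. Label 0 = background."""

    volume: VoxelVolume
    names: dict[int, str]

    def __post_init__(self) -> None:
        if not np.issubdtype(np.asarray(self.volume.values).dtype, np.integer):
            raise ValueError("labelmap values must be integers")
        if 0 in self.names:
            raise ValueError("label 0 is reserved for background")

    def mask(self, region: str) -> VoxelVolume:
        for label, name in self.names.items():
            if name == region:
                return self.volume.copy(values=(self.volume.values == label))
        raise KeyError(f"unknown region name {region!r}")

    def region_names(self) -> list[str]:
        return [self.names[k] for k in sorted(self.names)]


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"bspline3": 3, "linear": 1, "nearest": 0}


def resample(
    volume: VoxelVolume,
    new_spacing,
    interpolation: str = "bspline3",
) -> VoxelVolume:
    """Resample onto a grid with ``new_spacing`` covering the same world extent.

    Interpolation is one of ``bspline3`` (cubic B-spline, the default used for
    image intensities), ``linear`` or ``nearest`` (required for labelmaps).
    World geometry is preserved: the first output voxel center sits at the
    position of the first input voxel center.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    new_spacing = np.broadcast_to(
        np.asarray(new_spacing, dtype=float), (3,)
    ).astype(float)
    if np.any(new_spacing <= 0):
        raise ValueError("new_spacing must be positive")
    order = _INTERP_ORDER[interpolation]
    extent = np.asarray(volume.shape) * volume.spacing
    new_shape = np.maximum(np.round(extent / new_spacing).astype(int), 1)
    # index coordinates of the new voxel centers in the old grid
    coords = np.meshgrid(
        *[
            (np.arange(n) * s) / olds
            for n, s, olds in zip(new_shape, new_spacing, volume.spacing)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        np.asarray(volume.values, dtype=float),
        coords,
        order=order,
        mode="nearest",
    )
    if order == 0:
        out = out.astype(volume.values.dtype)
    return VoxelVolume(
        values=out, spacing=new_spacing, origin=volume.origin, axes=volume.axes
    )


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_KEY_COLUMNS = ("subject", "side", "sex", "tiv_cm3")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the (subject, side) keyed cohort table invariants."""
    for col in COHORT_KEY_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"cohort table missing column {col!r}")
    if not table["side"].isin(["L", "R"]).all():
        raise FormatError("side must be 'L' or 'R'")
    if not table["sex"].isin(["F", "M"]).all():
        raise FormatError("sex must be 'F' or 'M'")
    if table.duplicated(subset=["subject", "side"]).any():
        raise FormatError("duplicated (subject, side) rows")
    return table


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_cohort_table(table).to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path))
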