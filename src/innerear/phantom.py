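"""Parametric bony-labyrinth phantoms with analytic ground truth.

The phantom emulates the appearance of the inner ear in high-resolution MRI:
a bright fluid-filled labyrinth (three semicircular canals with ampullary
bulges and a common crus, an ellipsoidal vestibule housing utricle and
saccule, and a conical-spiral cochlea) on a dark background.  Three aligned
channels are rendered: ``t2like`` (bright labyrinth), ``cisslike`` (identical
but with the thin inter-scalae gap rendered dark, mimicking the separation of
scala tympani and scala vestibuli in steady-state imaging) and ``t1like``
(low contrast).  Gaussian blur models the point-spread function and additive
Gaussian noise sets the SNR.

Each phantom carries its ground truth: named landmarks for every measurement
endpoint of the morphometry protocol, watertight region meshes, and a table
of analytically known measures.  Cohorts of phantoms couple overall size to a
total-intracranial-volume (TIV) covariate so that the cohort statistics have
a known generating model.

Geometry conventions
--------------------
Right-ear anatomy is laid out in a canonical RAS mm frame (vestibule center
near the origin); ``side="left"`` mirrors everything about the mid-sagittal
plane of the image grid, so a left phantom is the voxel-exact mirror of its
right twin and has identical true measures.  Each semicircular canal is a
240-degree torus arc with hemispherical end caps; its "height" and "width"
truths are the outer bounding extents of the arc in its plane (height along
the arc apex direction, width across it), so that the conventional radius
measure 0.25*(height+width) equals the canal radius parameter exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import LandmarkSet, VoxelVolume

__all__ = [
    "PhantomParams",
    "PhantomTruth",
    "CohortSpec",
    "CohortEntry",
    "generate_phantom",
    "generate_cohort",
    "phantom_region_masks",
    "true_measures",
    "make_truth",
    "REGION_NAMES",
    "REID_LANDMARK_NAMES",
    "CHANNEL_INTENSITY",
]

# Nominal (background, tissue) intensity per channel.  Chosen so that the
# noiseless contrast regimes resemble clinical T2 / CISS / T1 appearance of
# labyrinthine fluid; configurable by editing a copy of this mapping.
CHANNEL_INTENSITY: dict[str, tuple[float, float]] = {
    "t2like": (0.10, 1.00),
    "cisslike": (0.06, 1.00),
    "t1like": (0.35, 0.58),
}

# Additive noise levels (intensity units) that put the measured in-ROI SNR of
# the t2like channel at the single-subject regime (~2.5) and at SNR ~4,
# given the intensity constants and default blur above.
NOISE_SIGMA_INDIVIDUAL = 0.29
NOISE_SIGMA_SNR4 = 0.135

REGION_NAMES = (
    "scc_ant",
    "scc_post",
    "scc_lat",
    "ampulla_ant",
    "ampulla_post",
    "ampulla_lat",
    "common_crus",
    "utricle",
    "saccule",
    "scala_vestibuli",
    "scala_tympani",
    "cochlear_duct",
    "cupula",
)

REID_LANDMARK_NAMES = (
    "infraorbital_left",
    "infraorbital_right",
    "auditory_meatus_left",
    "auditory_meatus_right",
)

# Grid center of the canonical layout (mm); constant so that left/right
# mirrors land on the same voxel lattice.
_GRID_CENTER = np.array([0.8, 2.3, 2.4])

# Arc half-angle of each semicircular canal (degrees).  The canals are open
# rings, not full circles; 120 deg half-angle (240 deg arc) is an assumption
# exposed here as a module constant.
_ARC_HALF_DEG = 120.0

_COCHLEA_ELLIPTICITY = 0.78  # minor/major axis ratio of the basal turn
_COCHLEA_RADIAL_TAPER = 0.75  # fractional shrink of spiral radius at apex
_COCHLEA_LUMEN_TAPER = 0.60  # fractional shrink of tube radius at apex
_CUPULA_FACTOR = 2.2  # apex dome radius as a multiple of the apical lumen


@dataclass
class PhantomParams:
    """Anatomy and imaging parameters of one phantom (all lengths in mm)."""

    scc_radius_ant: float = 3.7
    scc_radius_post: float = 3.7
    scc_radius_lat: float = 2.9
    scc_lumen_radius: float = 0.65
    ampulla_radius_ant: float = 0.94
    ampulla_radius_post: float = 0.81
    ampulla_radius_lat: float = 0.94
    vestibule_semiaxes: tuple[float, float, float] = (1.54, 2.695, 1.50)
    cochlea_base_diameter: float = 7.69
    cochlea_lumen_radius: float = 0.95
    cochlea_height: float = 3.06
    cochlea_turns: float = 2.57
    scala_gap: float = 0.45
    common_crus_length: float = 2.3
    common_crus_width: float = 2.1
    global_scale: float = 1.0
    noise_sigma: float = 0.29
    blur_fwhm: float = 0.5
    spacing: float = 0.2
    extent_mm: tuple[float, float, float] = (40.0, 40.0, 30.0)
    side: str = "right"

    def validate(self) -> None:
        lengths = {
            "scc_radius_ant": self.scc_radius_ant,
            "scc_radius_post": self.scc_radius_post,
            "scc_radius_lat": self.scc_radius_lat,
            "scc_lumen_radius": self.scc_lumen_radius,
            "ampulla_radius_ant": self.ampulla_radius_ant,
            "ampulla_radius_post": self.ampulla_radius_post,
            "ampulla_radius_lat": self.ampulla_radius_lat,
            "cochlea_base_diameter": self.cochlea_base_diameter,
            "cochlea_lumen_radius": self.cochlea_lumen_radius,
            "cochlea_height": self.cochlea_height,
            "scala_gap": self.scala_gap,
            "common_crus_length": self.common_crus_length,
            "common_crus_width": self.common_crus_width,
            "spacing": self.spacing,
        }
        for name, value in lengths.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if any(a <= 0 for a in self.vestibule_semiaxes):
            raise ValueError("vestibule semiaxes must be > 0")
        if self.spacing > self.scc_lumen_radius:
            raise ValueError(
                "lumen-unresolved: spacing "
                f"{self.spacing} mm exceeds the canal lumen radius "
                f"{self.scc_lumen_radius} mm (the lumen must span >= 1 voxel)"
            )
        if not (1.5 < self.cochlea_turns < 3.5):
            raise ValueError(f"cochlea_turns must be in (1.5, 3.5), got {self.cochlea_turns}")
        if not (0.7 < self.global_scale < 1.3):
            raise ValueError(f"global_scale must be in (0.7, 1.3), got {self.global_scale}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        # the measure radius 0.25*(H+W) = 0.808*rho + lumen must leave a
        # positive centerline radius
        for canal in ("ant", "post", "lat"):
            if self._centerline_radius(canal) <= 0:
                raise ValueError(
                    f"scc_radius_{canal} too small for lumen radius "
                    f"{self.scc_lumen_radius}"
                )

    # With a 240-degree arc the in-plane bounding extents of the tube are
    #   width  = 2*rho + 2*r      (across the arc; theta = +-90 deg reached)
    #   height = 1.5*rho + 2*r    (apex at +rho, chord side at -rho/2)
    # so 0.25*(height+width) = 0.875*rho + r.
    def _centerline_radius(self, canal: str) -> float:
        radius = getattr(self, f"scc_radius_{canal}")
        return (radius - self.scc_lumen_radius) / 0.875


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: landmarks, region meshes, measures."""

    landmarks: LandmarkSet
    region_meshes: dict[str, trimesh.Trimesh]
    true_measures: dict[str, float]


# ---------------------------------------------------------------------------
# Canonical right-ear layout
# ---------------------------------------------------------------------------


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class _Arc:
    """A 240-degree torus arc: center, apex direction d0, chord direction e,
    plane normal n, centerline radius rho, lumen radius r."""

    center: np.ndarray
    d0: np.ndarray
    e: np.ndarray
    n: np.ndarray
    rho: float
    r: float

    def point(self, theta):
        """Centerline point(s) at angle(s) theta (radians from the apex)."""
        theta = np.asarray(theta, dtype=float)
        offs = self.rho * (
            np.multiply.outer(np.cos(theta), self.d0)
            + np.multiply.outer(np.sin(theta), self.e)
        )
        return self.center + offs


def _arc_between(p_a: np.ndarray, p_b: np.ndarray, rho: float, r: float,
                 apex_hint: np.ndarray) -> _Arc:
    """Construct the 240-degree arc whose centerline endpoints are p_a, p_b,
    bulging toward ``apex_hint``."""
    half = math.radians(_ARC_HALF_DEG)
    chord = p_b - p_a
    chord_len = 2.0 * rho * math.sin(half)
    if not math.isclose(np.linalg.norm(chord), chord_len, rel_tol=1e-6):
        raise ValueError("endpoint separation inconsistent with arc radius")
    e = _unit(chord)
    mid = 0.5 * (p_a + p_b)
    n = _unit(np.cross(e, apex_hint - mid))
    d0 = _unit(np.cross(n, e))
    if np.dot(d0, apex_hint - mid) < 0:
        d0, n = -d0, -n
    center = mid - rho * math.cos(half) * d0  # cos(120 deg) = -1/2
    return _Arc(center=center, d0=d0, e=e, n=n, rho=rho, r=r)


class _CochleaGeom:
    """Dense sampling of the conical-spiral cochlea centerline.

    The centerline is an elliptical spiral ``c(t) = m0 + A(t) cos t e1 +
    B(t) sin t e2 + z(t) m`` for t in [0, 2 pi turns], with linearly tapering
    spiral radii and tube radius.  Frames (n1 radial, n2 along-axis) define
    the inter-scalae gap sheet: points with |(p-c).n2| <= gap/2 belong to the
    gap, and the scalae are the two sides of it.
    """

    def __init__(self, params: PhantomParams, m0, m_axis, n_samples=800):
        s = params.global_scale
        self.m0 = np.asarray(m0) * s
        self.m = _unit(m_axis)
        self.A0 = 0.5 * params.cochlea_base_diameter * s
        self.B0 = _COCHLEA_ELLIPTICITY * self.A0
        self.h = params.cochlea_height * s
        self.r0 = params.cochlea_lumen_radius * s
        self.t_max = 2.0 * math.pi * params.cochlea_turns
        self.gap = params.scala_gap * s
        # interscalar septum: where neighbouring turns come closer than this
        # bone-thickness margin, the space between them reads as dark bone
        self.septum_margin = 0.3 * s
        e1 = np.array([0.0, 1.0, 0.0])
        e1 = _unit(e1 - np.dot(e1, self.m) * self.m)
        self.e1 = e1
        self.e2 = np.cross(self.m, e1)
        self.t = np.linspace(0.0, self.t_max, n_samples)
        self.points = self._centerline(self.t)
        self.radii = self.tube_radius(self.t)
        # tangent frames
        tangent = np.gradient(self.points, self.t, axis=0)
        tangent /= np.linalg.norm(tangent, axis=1)[:, None]
        n2 = self.m[None, :] - (tangent @ self.m)[:, None] * tangent
        n2 /= np.linalg.norm(n2, axis=1)[:, None]
        self.n2 = n2
        self.n1 = np.cross(n2, tangent)
        # which n2 sign points superior (world +z); constant for our tilts
        self.upper_sign = float(np.sign(np.median(self.n2 @ np.array([0, 0, 1.0]))))
        self._tree: cKDTree | None = None
        # per-turn trees: adjacent spiral turns may touch; points claimed by
        # two turns form the interscalar septum (dark in the CISS channel)
        self._turn_of = np.floor(self.t / (2.0 * math.pi)).astype(int)
        self._turn_trees = [
            (cKDTree(self.points[self._turn_of == k]),
             np.flatnonzero(self._turn_of == k))
            for k in range(int(self._turn_of.max()) + 1)
        ]

    def spiral_radii(self, t):
        frac = np.asarray(t) / self.t_max
        a = self.A0 * (1.0 - _COCHLEA_RADIAL_TAPER * frac)
        return a, _COCHLEA_ELLIPTICITY * a

    def tube_radius(self, t):
        frac = np.asarray(t) / self.t_max
        return self.r0 * (1.0 - _COCHLEA_LUMEN_TAPER * frac)

    def _centerline(self, t):
        a, b = self.spiral_radii(t)
        z = self.h * np.asarray(t) / self.t_max
        return (
            self.m0
            + (a * np.cos(t))[:, None] * self.e1
            + (b * np.sin(t))[:, None] * self.e2
            + z[:, None] * self.m
        )

    def wall_point(self, t: float) -> np.ndarray:
        """Outer lateral-wall point at spiral angle t (radial extreme)."""
        c = self._centerline(np.array([t]))[0]
        axial = self.m0 + np.dot(c - self.m0, self.m) * self.m
        radial = _unit(c - axial)
        return c + self.tube_radius(t) * radial

    @property
    def apex(self) -> np.ndarray:
        """Top of the apical dome (the cochlear cupula)."""
        return self.points[-1] + self.radii[-1] * self.m * np.sign(self.h) * 1.0

    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def classify(self, pts: np.ndarray):
        """Return (inside_tube, signed_gap_coordinate, n_turn_claims).

        ``n_turn_claims`` counts how many spiral turns contain the point;
        values >= 2 mark the interscalar septum where adjacent turns touch.
        """
        dist, idx = self.tree().query(pts, k=1)
        inside = dist <= self.radii[idx]
        w = pts - self.points[idx]
        b = np.einsum("ij,ij->i", w, self.n2[idx]) * self.upper_sign
        claims = np.zeros(len(pts), dtype=np.int8)
        for tree, sample_idx in self._turn_trees:
            d_k, i_k = tree.query(pts, k=1)
            near = d_k <= self.radii[sample_idx[i_k]] + self.septum_margin
            claims += near.astype(np.int8)
        return inside, b, claims


class _Layout:
    """All primitives of one phantom in world coordinates (right-ear frame,
    already scaled by ``global_scale``)."""

    def __init__(self, params: PhantomParams):
        params.validate()
        self.params = params
        s = params.global_scale
        r = params.scc_lumen_radius * s
        self.vest_center = np.zeros(3)
        self.vest_axes = np.asarray(params.vestibule_semiaxes) * s

        def arc(canal: str, p_a, p_b, apex_hint) -> _Arc:
            rho = params._centerline_radius(canal) * s
            half = math.radians(_ARC_HALF_DEG)
            p_a, p_b = np.asarray(p_a) * s, np.asarray(p_b) * s
            # rescale the endpoint pair about its midpoint to the exact chord
            mid = 0.5 * (p_a + p_b)
            d = p_b - p_a
            d *= (2.0 * rho * math.sin(half)) / np.linalg.norm(d)
            return _arc_between(mid - d / 2, mid + d / 2, rho, r,
                                np.asarray(apex_hint) * s)

        # endpoints chosen so canal limbs land on the vestibule / common crus
        self.arcs = {
            "lat": arc("lat", (1.05, 2.1, 0.8), (1.05, -2.354, 0.8), (6.0, 0.0, 0.8)),
            "ant": arc("ant", (2.36, 3.34, -0.19), (-1.3, -0.25, 3.0), (2.5, 3.5, 7.0)),
            "post": arc("post", (2.07, -3.05, -0.77), (-1.3, 0.25, 3.0), (2.7, -3.7, 6.0)),
        }
        # ampullae sit at the arc end closest to the vestibule
        self.ampulla_center = {}
        half = math.radians(_ARC_HALF_DEG)
        for canal, a in self.arcs.items():
            ends = [a.point(half), a.point(-half)]
            which = int(np.argmin([np.linalg.norm(e) for e in ends]))
            self.ampulla_center[canal] = ends[which]
        self.ampulla_radius = {
            c: getattr(params, f"ampulla_radius_{c}") * s for c in self.arcs
        }

        self.crus_bottom = np.array([-1.3, 0.0, 0.9]) * s
        self.crus_top = self.crus_bottom + np.array(
            [0.0, 0.0, params.common_crus_length]
        ) * s
        self.crus_radius = 0.5 * params.common_crus_width * s

        self.utricle_center = np.array([0.0, -0.3, 0.5]) * s
        self.utricle_axes = np.array([1.05, 2.2, 0.92]) * s
        self.saccule_center = np.array([0.0, 1.2, -0.55]) * s
        self.saccule_radius = 0.85 * s

        self.cochlea = _CochleaGeom(
            params, m0=(-0.195, 5.671, 1.173), m_axis=(0.25, 0.5, -0.829)
        )

        # thin bridge tubes that keep the rendered labyrinth connected
        lat_far = [e for e in
                   [self.arcs["lat"].point(half), self.arcs["lat"].point(-half)]
                   if np.linalg.norm(e - self.ampulla_center["lat"]) > 1e-9][0]
        self.connectors = [
            (self.ampulla_center["ant"], np.array([0.9, 1.9, 0.0]) * s, 0.6 * s),
            (self.ampulla_center["post"], np.array([0.8, -1.9, -0.45]) * s, 0.6 * s),
            (self.ampulla_center["lat"], np.array([0.5, 1.6, 0.5]) * s, 0.6 * s),
            (lat_far, np.array([0.5, -1.6, 0.5]) * s, 0.6 * s),
            (self.cochlea._centerline(np.array([math.pi]))[0],
             np.array([0.2, 1.7, -0.6]) * s, 0.6 * s),
        ]

    # -- inside tests (vectorized over an (N, 3) point array) ---------------

    def inside_arc(self, pts, canal: str) -> np.ndarray:
        a = self.arcs[canal]
        half = math.radians(_ARC_HALF_DEG)
        u = pts - a.center
        x1 = u @ a.d0
        x2 = u @ a.e
        x3 = u @ a.n
        theta = np.arctan2(x2, x1)
        in_span = np.abs(theta) <= half
        ring = (np.hypot(x1, x2) - a.rho) ** 2 + x3 ** 2 <= a.r ** 2
        d_end = np.minimum(
            np.linalg.norm(pts - a.point(half), axis=1),
            np.linalg.norm(pts - a.point(-half), axis=1),
        )
        return (in_span & ring) | (d_end <= a.r)

    def inside_ellipsoid(self, pts, center, axes) -> np.ndarray:
        return np.sum(((pts - center) / axes) ** 2, axis=1) <= 1.0

    def inside_segment(self, pts, p_a, p_b, radius) -> np.ndarray:
        d = p_b - p_a
        length2 = float(d @ d)
        t = np.clip((pts - p_a) @ d / length2, 0.0, 1.0)
        closest = p_a + t[:, None] * d
        return np.linalg.norm(pts - closest, axis=1) <= radius

    def region_inside(self, pts: np.ndarray, region: str) -> np.ndarray:
        if region in ("scc_ant", "scc_post", "scc_lat"):
            return self.inside_arc(pts, region.split("_")[1])
        if region.startswith("ampulla_"):
            canal = region.split("_")[1]
            c = self.ampulla_center[canal]
            return np.linalg.norm(pts - c, axis=1) <= self.ampulla_radius[canal]
        if region == "common_crus":
            return self.inside_segment(pts, self.crus_bottom, self.crus_top,
                                       self.crus_radius)
        if region == "vestibule":
            return self.inside_ellipsoid(pts, self.vest_center, self.vest_axes)
        if region == "utricle":
            return self.inside_ellipsoid(pts, self.utricle_center, self.utricle_axes)
        if region == "saccule":
            return np.linalg.norm(pts - self.saccule_center, axis=1) <= self.saccule_radius
        if region in ("cochlea", "scala_vestibuli", "scala_tympani", "gap",
                      "cochlear_duct"):
            inside, b, claims = self.cochlea.classify(pts)
            half_gap = 0.5 * self.cochlea.gap
            septum = claims >= 2
            if region == "cochlea":
                return inside
            if region == "gap":
                return inside & ((np.abs(b) <= half_gap) | septum)
            if region == "scala_vestibuli":
                return inside & (b > half_gap) & ~septum
            if region == "scala_tympani":
                return inside & (b < -half_gap) & ~septum
            # cochlear duct: a thin tube within the gap sheet near the outer wall
            dist, idx = self.cochlea.tree().query(pts, k=1)
            duct_r = 0.45 * self.params.global_scale
            w = pts - self.cochlea.points[idx]
            a_coord = np.einsum("ij,ij->i", w, self.cochlea.n1[idx])
            offset = 0.35 * self.cochlea.radii[idx]
            return inside & (np.hypot(a_coord - offset, b) <= duct_r)
        if region == "cupula":
            apex_c = self.cochlea.points[-1]
            r_cup = _CUPULA_FACTOR * self.cochlea.radii[-1]
            return np.linalg.norm(pts - apex_c, axis=1) <= r_cup
        raise KeyError(f"unknown region {region!r}")

    def labyrinth_inside(self, pts: np.ndarray) -> np.ndarray:
        out = self.inside_ellipsoid(pts, self.vest_center, self.vest_axes)
        for canal in ("ant", "post", "lat"):
            out |= self.inside_arc(pts, canal)
            c = self.ampulla_center[canal]
            out |= np.linalg.norm(pts - c, axis=1) <= self.ampulla_radius[canal]
        out |= self.inside_segment(pts, self.crus_bottom, self.crus_top,
                                   self.crus_radius)
        inside_c, _, _ = self.cochlea.classify(pts)
        out |= inside_c
        for p_a, p_b, radius in self.connectors:
            out |= self.inside_segment(pts, p_a, p_b, radius)
        return out

    def bounding_box(self, margin: float = 0.0):
        """Axis-aligned bounds of all primitives (sampled densely)."""
        pts = [self.vest_center + self.vest_axes, self.vest_center - self.vest_axes]
        half = math.radians(_ARC_HALF_DEG)
        thetas = np.linspace(-half, half, 64)
        for canal, a in self.arcs.items():
            ring = a.point(thetas)
            pts.append(ring + a.r)
            pts.append(ring - a.r)
        pts.append(self.cochlea.points + self.cochlea.radii[:, None])
        pts.append(self.cochlea.points - self.cochlea.radii[:, None])
        pts.append(np.atleast_2d(self.crus_top + self.crus_radius))
        pts.append(np.atleast_2d(self.crus_bottom - self.crus_radius))
        allp = np.vstack([np.atleast_2d(p) for p in pts])
        return allp.min(axis=0) - margin, allp.max(axis=0) + margin


# ---------------------------------------------------------------------------
# Ground-truth landmarks and measures
# ---------------------------------------------------------------------------


def _canal_landmarks(layout: _Layout, canal: str) -> dict[str, np.ndarray]:
    a = layout.arcs[canal]
    lm = {}
    prefix = f"scc_{canal}"
    # width: outer-wall extremes across the arc (theta = +-90 deg)
    lm[f"{prefix}_width_a"] = a.center + (a.rho + a.r) * a.e
    lm[f"{prefix}_width_b"] = a.center - (a.rho + a.r) * a.e
    # height: apex outer wall vs the projected chord-side extreme; the second
    # point is the bounding-plane guide point (the visual convention measures
    # the box extent, not a surface-to-surface chord)
    lm[f"{prefix}_height_a"] = a.center + (a.rho + a.r) * a.d0
    lm[f"{prefix}_height_b"] = a.center - (0.5 * a.rho + a.r) * a.d0
    for k, theta in enumerate((-math.pi / 3, 0.0, math.pi / 3), start=1):
        p = a.point(theta)[()]
        g = _unit(math.cos(theta) * a.d0 + math.sin(theta) * a.e)
        lm[f"{prefix}_internal_width_{k}_a"] = p + a.r * g
        lm[f"{prefix}_internal_width_{k}_b"] = p - a.r * g
        lm[f"{prefix}_internal_height_{k}_a"] = p + a.r * a.n
        lm[f"{prefix}_internal_height_{k}_b"] = p - a.r * a.n
    return lm


def _truth_landmarks(layout: _Layout) -> dict[str, np.ndarray]:
    lm: dict[str, np.ndarray] = {}
    for canal in ("ant", "post", "lat"):
        lm.update(_canal_landmarks(layout, canal))

    lm["common_crus_length_a"] = layout.crus_bottom
    lm["common_crus_length_b"] = layout.crus_top
    ez = np.array([0.0, 0.0, 1.0])
    for k, frac in enumerate((0.85, 0.5, 0.15), start=1):  # superior..inferior
        p = layout.crus_bottom + frac * (layout.crus_top - layout.crus_bottom)
        lm[f"common_crus_width_{k}_a"] = p + layout.crus_radius * np.array([1.0, 0, 0])
        lm[f"common_crus_width_{k}_b"] = p - layout.crus_radius * np.array([1.0, 0, 0])

    ax = layout.vest_axes
    lm["vestibule_length_a"] = layout.vest_center + np.array([0, ax[1], 0])
    lm["vestibule_length_b"] = layout.vest_center - np.array([0, ax[1], 0])
    lm["vestibule_width_a"] = layout.vest_center + np.array([ax[0], 0, 0])
    lm["vestibule_width_b"] = layout.vest_center - np.array([ax[0], 0, 0])

    coch = layout.cochlea
    lm["cochlea_round_window"] = coch.wall_point(0.0)
    lm["cochlea_length_a"] = lm["cochlea_round_window"]
    lm["cochlea_length_b"] = coch.wall_point(math.pi)
    lm["cochlea_width_a"] = coch.wall_point(math.pi / 2)
    lm["cochlea_width_b"] = coch.wall_point(3 * math.pi / 2)
    lm["cochlea_modiolus"] = coch.m0
    lm["cochlea_nerve_foramen"] = coch.m0
    lm["cochlea_apex"] = _apex_point(coch)
    lm["cochlea_height_oblique_a"] = lm["cochlea_nerve_foramen"]
    lm["cochlea_height_oblique_b"] = lm["cochlea_apex"]
    for k, t in enumerate(np.linspace(0.0, 2 * math.pi, 7)):
        lm[f"cochlea_basal_{k + 1}"] = coch._centerline(np.array([t]))[0]
    n_contour = 72
    for k, t in enumerate(np.linspace(0.0, 2 * math.pi, n_contour, endpoint=False)):
        lm[f"cochlea_contour_{k:02d}"] = coch.wall_point(t)

    # coronal height: vertical extent of the cochlea (basal + upper turns),
    # reported as a landmark pair projected onto a shared coronal line
    zs_top = coch.points[:, 2] + coch.radii
    zs_bot = coch.points[:, 2] - coch.radii
    z_top, z_bot = float(zs_top.max()), float(zs_bot.min())
    xy = coch.m0[:2]
    lm["cochlea_height_coronal_a"] = np.array([xy[0], xy[1], z_top])
    lm["cochlea_height_coronal_b"] = np.array([xy[0], xy[1], z_bot])

    # total inner-ear length: most posterior point of the posterior canal to
    # the most anterior point of the cochlea
    a = layout.arcs["post"]
    half = math.radians(_ARC_HALF_DEG)
    thetas = np.linspace(-half, half, 2048)
    ring = a.point(thetas)
    # outer-wall posterior extreme of the tube
    post_idx = int(np.argmin(ring[:, 1]))
    radial = _unit(ring[post_idx] - a.center - np.dot(
        ring[post_idx] - a.center, a.n) * a.n)
    lm["inner_ear_length_total_a"] = ring[post_idx] + a.r * np.array([0.0, -1.0, 0.0])
    wall_hi = coch.points + coch.radii[:, None] * np.array([0.0, 1.0, 0.0])
    ant_idx = int(np.argmax(wall_hi[:, 1]))
    lm["inner_ear_length_total_b"] = wall_hi[ant_idx]

    # Reid-plane landmarks: four points in the plane of the lateral canal
    # (the standard coplanarity assumption), at head scale
    lat = layout.arcs["lat"]
    c, n = lat.center, lat.n
    u = _unit(np.cross(n, np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9
                       else np.array([1.0, 0.0, 0.0])))
    v = np.cross(n, u)
    lm["auditory_meatus_right"] = c + 12.0 * u
    lm["auditory_meatus_left"] = c - 12.0 * u
    lm["infraorbital_right"] = c + 60.0 * v + 10.0 * u
    lm["infraorbital_left"] = c + 60.0 * v - 10.0 * u
    return lm


def _apex_point(coch: _CochleaGeom) -> np.ndarray:
    """Tip of the apical dome: the centerline end pushed along the modiolar
    axis away from the base."""
    axis_dir = coch.m if np.dot(coch.points[-1] - coch.m0, coch.m) > 0 else -coch.m
    return coch.points[-1] + coch.radii[-1] * axis_dir


_DIST_MEASURES_SIMPLE = tuple(
    [f"scc_{c}_{d}" for c in ("ant", "post", "lat") for d in ("height", "width")]
    + [f"scc_{c}_internal_{d}_{k}" for c in ("ant", "post", "lat")
       for d in ("width", "height") for k in (1, 2, 3)]
    + ["common_crus_length"]
    + [f"common_crus_width_{k}" for k in (1, 2, 3)]
    + ["vestibule_length", "vestibule_width", "inner_ear_length_total",
       "cochlea_height_coronal", "cochlea_height_oblique",
       "cochlea_length", "cochlea_width"]
)


def true_measures(params: PhantomParams, volumes: bool = True,
                  n_mc: int = 400_000) -> dict[str, float]:
    """Analytic ground-truth measure table for a phantom.

    Distance measures come from the closed-form landmark construction; the
    volume measures of composite structures (cochlea, whole labyrinth) use a
    deterministic Monte-Carlo estimate over the union of primitives (seeded,
    scale-exact).  ``volumes=False`` skips the volume entries, which is much
    faster and is what cohort simulation uses.
    """
    layout = _Layout(params)
    lm = _truth_landmarks(layout)
    out: dict[str, float] = {}
    for name in _DIST_MEASURES_SIMPLE:
        out[name] = float(np.linalg.norm(lm[f"{name}_a"] - lm[f"{name}_b"]))
    for canal in ("ant", "post", "lat"):
        out[f"scc_{canal}_radius"] = 0.25 * (
            out[f"scc_{canal}_height"] + out[f"scc_{canal}_width"]
        )
    if volumes:
        for canal in ("ant", "post", "lat"):
            r = layout.ampulla_radius[canal]
            out[f"vol_ampulla_{canal}"] = 4.0 / 3.0 * math.pi * r ** 3
        out["vol_saccule"] = 4.0 / 3.0 * math.pi * layout.saccule_radius ** 3
        out["vol_utricle"] = 4.0 / 3.0 * math.pi * float(np.prod(layout.utricle_axes))
        out["vol_cochlea"] = _mc_volume(
            layout, lambda pts: layout.region_inside(pts, "cochlea"),
            *_cochlea_bbox(layout), n=max(n_mc // 2, 1000),
        )
        out["vol_inner_ear_total"] = _mc_volume(
            layout, layout.labyrinth_inside, *layout.bounding_box(), n=n_mc
        )
    return out


def _cochlea_bbox(layout: _Layout):
    pts = layout.cochlea.points
    r = layout.cochlea.radii[:, None]
    return (pts - r).min(axis=0), (pts + r).max(axis=0)


def _mc_volume(layout, inside_fn, lo, hi, n: int) -> float:
    """Deterministic Monte-Carlo volume of an inside-function over a box.

    The sample is drawn in unit-cube coordinates with a fixed seed and mapped
    into the (geometry-dependent) box, so the estimate scales exactly as s^3
    under isotropic scaling of the geometry.
    """
    rng = np.random.default_rng(123456789)
    unit = rng.random((n, 3))
    pts = lo + unit * (hi - lo)
    frac = float(np.count_nonzero(inside_fn(pts))) / n
    return frac * float(np.prod(hi - lo))


# ---------------------------------------------------------------------------
# Meshes
# ---------------------------------------------------------------------------


def _sweep_mesh(path: np.ndarray, n1: np.ndarray, n2: np.ndarray,
                sections: np.ndarray, round_caps: bool = False,
                n_cap: int = 6) -> trimesh.Trimesh:
    """Watertight sweep of per-station convex cross-sections along a path.

    ``sections`` has shape (n_stations, k, 2): 2-D polygon coordinates in the
    (n1, n2) frame of each station.  End caps are triangle fans about the
    polygon centroid; with ``round_caps`` the tube ends are closed by
    near-hemispherical domes (section shrink along the end tangent) so the
    mesh matches the capsule-style analytic inside tests of the phantom.
    Watertightness requires star-shaped cross-sections.
    """
    if round_caps:
        path, n1, n2, sections = _with_round_caps(path, n1, n2, sections, n_cap)
    m, k = sections.shape[0], sections.shape[1]
    verts = (
        path[:, None, :]
        + sections[:, :, 0, None] * n1[:, None, :]
        + sections[:, :, 1, None] * n2[:, None, :]
    ).reshape(m * k, 3)
    faces = []
    for i in range(m - 1):
        base0, base1 = i * k, (i + 1) * k
        for j in range(k):
            jn = (j + 1) % k
            faces.append([base0 + j, base1 + j, base1 + jn])
            faces.append([base0 + j, base1 + jn, base0 + jn])
    c0 = len(verts)
    verts = np.vstack([verts, path[0], path[-1]])
    for j in range(k):
        jn = (j + 1) % k
        faces.append([c0, (0) * k + jn, (0) * k + j])
        faces.append([c0 + 1, (m - 1) * k + j, (m - 1) * k + jn])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _with_round_caps(path, n1, n2, sections, n_cap: int):
    """Append dome stations at both tube ends (quarter-circle shrink)."""
    angles = np.linspace(0.0, math.pi / 2, n_cap + 1)[1:]

    def cap(end: int):
        other = 1 if end == 0 else -2
        tangent = _unit(path[end] - path[other])
        sec = sections[end]
        cen = sec.mean(axis=0)
        r_eff = float(np.linalg.norm(sec - cen, axis=1).max())
        stations_p = np.asarray(
            [path[end] + r_eff * math.sin(a) * tangent for a in angles])
        stations_s = np.asarray([cen + (sec - cen) * math.cos(a) for a in angles])
        if end == 0:
            stations_p, stations_s = stations_p[::-1], stations_s[::-1]
        return (stations_p,
                np.repeat(n1[end][None], n_cap, axis=0),
                np.repeat(n2[end][None], n_cap, axis=0),
                stations_s)

    head, tail = cap(0), cap(-1)
    path = np.vstack([head[0], path, tail[0]])
    n1 = np.vstack([head[1], n1, tail[1]])
    n2 = np.vstack([head[2], n2, tail[2]])
    sections = np.concatenate([head[3], sections, tail[3]], axis=0)
    return path, n1, n2, sections


def _circle_sections(radii: np.ndarray, k: int = 24) -> np.ndarray:
    phi = np.linspace(0.0, 2 * math.pi, k, endpoint=False)
    ring = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    return radii[:, None, None] * ring[None, :, :]


def _arc_mesh(a: _Arc, n_path: int = 96, k: int = 24) -> trimesh.Trimesh:
    half = math.radians(_ARC_HALF_DEG)
    thetas = np.linspace(-half, half, n_path)
    path = a.point(thetas)
    radial = np.cos(thetas)[:, None] * a.d0 + np.sin(thetas)[:, None] * a.e
    n1 = radial
    n2 = np.broadcast_to(a.n, path.shape).copy()
    sections = _circle_sections(np.full(n_path, a.r), k)
    return _sweep_mesh(path, n1, n2, sections, round_caps=True)


def _half_disc_sections(radii: np.ndarray, chord: float, sign: float,
                        k: int = 16) -> np.ndarray:
    """Cross-sections of a tube cut by the plane n2 = sign*chord, keeping the
    side away from the gap."""
    out = np.zeros((len(radii), k + 2, 2))
    for i, r in enumerate(radii):
        c = min(chord, 0.95 * r)
        x_c = math.sqrt(max(r * r - c * c, 1e-12))
        ang0 = math.atan2(c, x_c)
        angs = np.linspace(ang0, math.pi - ang0, k)
        pts = np.stack([r * np.cos(angs), r * np.sin(angs)], axis=1)
        poly = np.vstack([[x_c, c], pts, [-x_c, c]])
        if sign < 0:
            poly = poly[::-1] * np.array([1.0, -1.0])
        out[i] = poly
    return out


def _cochlea_meshes(coch: _CochleaGeom, global_scale: float
                    ) -> dict[str, trimesh.Trimesh]:
    idx = np.arange(0, len(coch.points), 4)
    path, n1, n2 = coch.points[idx], coch.n1[idx], coch.n2[idx]
    radii = coch.radii[idx]
    half_gap = 0.5 * coch.gap
    up = coch.upper_sign
    meshes = {
        "scala_vestibuli": _sweep_mesh(
            path, n1, n2 * up, _half_disc_sections(radii, half_gap, +1.0),
            round_caps=True),
        "scala_tympani": _sweep_mesh(
            path, n1, n2 * up, _half_disc_sections(radii, half_gap, -1.0),
            round_caps=True),
    }
    duct_r = 0.45 * global_scale
    duct_path = path + (0.35 * radii)[:, None] * n1
    meshes["cochlear_duct"] = _sweep_mesh(
        duct_path, n1, n2, _circle_sections(np.full(len(idx), duct_r), 16),
        round_caps=True)
    cup = trimesh.creation.icosphere(
        subdivisions=3, radius=_CUPULA_FACTOR * float(coch.radii[-1]))
    cup.apply_translation(coch.points[-1])
    meshes["cupula"] = cup
    return meshes


def _region_meshes(layout: _Layout) -> dict[str, trimesh.Trimesh]:
    meshes: dict[str, trimesh.Trimesh] = {}
    for canal in ("ant", "post", "lat"):
        meshes[f"scc_{canal}"] = _arc_mesh(layout.arcs[canal])
        sphere = trimesh.creation.icosphere(
            subdivisions=3, radius=layout.ampulla_radius[canal])
        sphere.apply_translation(layout.ampulla_center[canal])
        meshes[f"ampulla_{canal}"] = sphere
    axis = layout.crus_top - layout.crus_bottom
    n_path = 12
    path = layout.crus_bottom + np.linspace(0, 1, n_path)[:, None] * axis
    n1 = np.broadcast_to(np.array([1.0, 0.0, 0.0]), path.shape).copy()
    n2 = np.broadcast_to(np.array([0.0, 1.0, 0.0]), path.shape).copy()
    meshes["common_crus"] = _sweep_mesh(
        path, n1, n2, _circle_sections(np.full(n_path, layout.crus_radius)),
        round_caps=True)
    utr = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    utr.apply_scale(layout.utricle_axes)
    utr.apply_translation(layout.utricle_center)
    meshes["utricle"] = utr
    sac = trimesh.creation.icosphere(subdivisions=3, radius=layout.saccule_radius)
    sac.apply_translation(layout.saccule_center)
    meshes["saccule"] = sac
    meshes.update(_cochlea_meshes(layout.cochlea, layout.params.global_scale))
    return meshes


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _make_grid(params: PhantomParams) -> VoxelVolume:
    extent = np.asarray(params.extent_mm, dtype=float)
    shape = np.round(extent / params.spacing).astype(int)
    spacing = np.full(3, params.spacing)
    origin = _GRID_CENTER - (shape - 1) * spacing / 2.0
    return VoxelVolume(values=np.zeros(shape, dtype=np.float32),
                       spacing=spacing, origin=origin)


def _mirror_map(grid: VoxelVolume):
    cx = grid.origin[0] + (grid.shape[0] - 1) * grid.spacing[0] / 2.0

    def refl(pts: np.ndarray) -> np.ndarray:
        pts = np.array(pts, dtype=float, copy=True)
        pts[..., 0] = 2.0 * cx - pts[..., 0]
        return pts

    return refl


def _rasterize_region(layout: _Layout, grid: VoxelVolume, region: str,
                      mirrored: bool) -> np.ndarray:
    """Boolean mask of a region on the grid, restricted to its bounding box."""
    if region == "labyrinth":
        lo, hi = layout.bounding_box(margin=0.5)
        fn = layout.labyrinth_inside
    else:
        lo, hi = _region_bbox(layout, region)
        fn = lambda pts: layout.region_inside(pts, region)  # noqa: E731
    refl = _mirror_map(grid) if mirrored else None
    if mirrored:
        lo_m = refl(np.array([hi[0], lo[1], lo[2]]))
        hi_m = refl(np.array([lo[0], hi[1], hi[2]]))
        lo_g, hi_g = np.minimum(lo_m, hi_m), np.maximum(lo_m, hi_m)
        lo_g[1:], hi_g[1:] = lo[1:], hi[1:]
    else:
        lo_g, hi_g = lo, hi
    i_lo = np.maximum(np.floor(grid.index_from_world(lo_g)).astype(int), 0)
    i_hi = np.minimum(np.ceil(grid.index_from_world(hi_g)).astype(int) + 1,
                      np.asarray(grid.shape))
    if np.any(i_hi <= i_lo):
        raise ValueError(
            f"phantom geometry for {region!r} lies outside the image grid; "
            "increase extent_mm or reduce global_scale"
        )
    axes_w = [grid.origin[d] + np.arange(i_lo[d], i_hi[d]) * grid.spacing[d]
              for d in range(3)]
    mesh = np.meshgrid(*axes_w, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    if mirrored:
        pts = refl(pts)
    sub = fn(pts).reshape([len(a) for a in axes_w])
    full = np.zeros(grid.shape, dtype=bool)
    full[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]] = sub
    return full


def _region_bbox(layout: _Layout, region: str):
    pad = 0.3
    if region in ("scc_ant", "scc_post", "scc_lat"):
        a = layout.arcs[region.split("_")[1]]
        half = math.radians(_ARC_HALF_DEG)
        ring = a.point(np.linspace(-half, half, 64))
        return ring.min(axis=0) - a.r - pad, ring.max(axis=0) + a.r + pad
    if region.startswith("ampulla_"):
        canal = region.split("_")[1]
        c, r = layout.ampulla_center[canal], layout.ampulla_radius[canal]
        return c - r - pad, c + r + pad
    if region == "common_crus":
        lo = np.minimum(layout.crus_bottom, layout.crus_top) - layout.crus_radius - pad
        hi = np.maximum(layout.crus_bottom, layout.crus_top) + layout.crus_radius + pad
        return lo, hi
    if region == "vestibule":
        return (layout.vest_center - layout.vest_axes - pad,
                layout.vest_center + layout.vest_axes + pad)
    if region == "utricle":
        return (layout.utricle_center - layout.utricle_axes - pad,
                layout.utricle_center + layout.utricle_axes + pad)
    if region == "saccule":
        c, r = layout.saccule_center, layout.saccule_radius
        return c - r - pad, c + r + pad
    lo, hi = _cochlea_bbox(layout)
    return lo - pad, hi + pad


def phantom_region_masks(params: PhantomParams, regions=None,
                         grid: VoxelVolume | None = None
                         ) -> dict[str, VoxelVolume]:
    """Rasterize ground-truth region masks ('labyrinth', 'cochlea', 'gap'
    and the atlas regions of :data:`REGION_NAMES`) on the phantom grid."""
    layout = _Layout(params)
    if grid is None:
        grid = _make_grid(params)
    mirrored = params.side == "left"
    if regions is None:
        regions = ("labyrinth",) + REGION_NAMES
    return {
        name: grid.copy(values=_rasterize_region(layout, grid, name, mirrored))
        for name in regions
    }


def make_truth(params: PhantomParams, meshes: bool = True,
               volumes: bool = True) -> PhantomTruth:
    """Assemble the ground truth (landmarks, region meshes, measure table)."""
    layout = _Layout(params)
    lm = _truth_landmarks(layout)
    region_meshes = _region_meshes(layout) if meshes else {}
    if params.side == "left":
        refl = _mirror_map(_make_grid(params))
        lm = {k: refl(v) for k, v in lm.items()}
        # swap the head-scale left/right landmark labels under mirroring
        for a, b in (("infraorbital_left", "infraorbital_right"),
                     ("auditory_meatus_left", "auditory_meatus_right")):
            lm[a], lm[b] = lm[b], lm[a]
        mirrored = {}
        for name, mesh in region_meshes.items():
            m = mesh.copy()
            m.vertices = refl(m.vertices)
            m.invert()
            mirrored[name] = m
        region_meshes = mirrored
    return PhantomTruth(
        landmarks=LandmarkSet(lm, frame="subject"),
        region_meshes=region_meshes,
        true_measures=true_measures(params, volumes=volumes),
    )


def generate_phantom(params: PhantomParams, seed: int = 0,
                     channels=("t2like", "cisslike", "t1like"),
                     truth_meshes: bool = True, truth_volumes: bool = True,
                     ) -> tuple[dict[str, VoxelVolume], PhantomTruth]:
    """Render the multi-channel phantom volumes plus their ground truth.

    With ``noise_sigma == 0`` the output is deterministic (independent of the
    seed), and a ``side='left'`` phantom is the voxel-exact sagittal mirror
    of its ``side='right'`` twin.
    """
    params.validate()
    layout = _Layout(params)
    grid = _make_grid(params)
    lo, hi = layout.bounding_box(margin=2.0 * params.blur_fwhm)
    g_lo = grid.origin - grid.spacing / 2.0
    g_hi = grid.origin + (np.asarray(grid.shape) - 0.5) * grid.spacing
    span = hi - lo
    if np.any(span > (g_hi - g_lo)):
        raise ValueError(
            "phantom geometry plus blur margin exceeds the image grid "
            f"(needs {span} mm, grid provides {g_hi - g_lo} mm)"
        )
    mirrored = params.side == "left"
    lab = _rasterize_region(layout, grid, "labyrinth", mirrored)
    gap = _rasterize_region(layout, grid, "gap", mirrored)
    sigma_vox = params.blur_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / params.spacing
    rng = np.random.default_rng(seed)
    out: dict[str, VoxelVolume] = {}
    for name in channels:
        bg, fg = CHANNEL_INTENSITY[name]
        img = np.full(grid.shape, bg, dtype=np.float64)
        img[lab] = fg
        if name == "cisslike":
            img[gap] = bg
        img = ndimage.gaussian_filter(img, sigma_vox)
        if params.noise_sigma > 0:
            img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
        out[name] = grid.copy(values=img.astype(np.float32))
    truth = make_truth(params, meshes=truth_meshes, volumes=truth_volumes)
    return out, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Generating model of a phantom cohort.

    Overall labyrinth size couples linearly to TIV
    (``global_scale = 1 + scale_tiv_slope * (TIV - tiv_mean)``), with sexes
    differing in mean TIV by ``sex_tiv_offset`` so that, at
    ``sex_effect == 0``, any sex difference in the measures is mediated
    entirely by TIV.  ``sex_effect`` and ``laterality_effect`` are
    multiplicative scale effects beyond TIV (0 = null).  ``scale_noise_sd``
    is TIV-independent biological scale variation and ``side_noise_sd`` is
    independent per-ear variation; both keep the simulated correlations and
    paired tests away from degenerate (r = 1 / zero-variance) regimes.
    """

    n_subjects: int = 30
    tiv_mean: float = 1450.0  # cm^3
    tiv_sd: float = 120.0
    scale_tiv_slope: float = 3.0e-4  # per cm^3
    sex_effect: float = 0.0
    laterality_effect: float = 0.0
    sex_tiv_offset: float = 100.0  # cm^3, M minus F mean TIV
    scale_noise_sd: float = 0.02
    side_noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.tiv_sd < 0:
            raise ValueError("tiv_sd must be >= 0")


@dataclass
class CohortEntry:
    subject: str
    side: str  # 'L' or 'R'
    sex: str  # 'F' or 'M'
    tiv_cm3: float
    params: PhantomParams
    true_measures: dict[str, float] = field(repr=False)

    def render(self, seed: int = 0, **kwargs):
        return generate_phantom(self.params, seed=seed, **kwargs)


def generate_cohort(spec: CohortSpec,
                    base_params: PhantomParams | None = None,
                    volumes: bool = False) -> list[CohortEntry]:
    """Draw a cohort of phantom ears (two per subject, left and right).

    Returns one :class:`CohortEntry` per ear carrying the drawn parameters
    and the analytic true measures; volumes are rendered lazily through
    :meth:`CohortEntry.render` so that statistical simulation stays cheap.
    """
    spec.validate()
    base = base_params if base_params is not None else PhantomParams()
    rng = np.random.default_rng(spec.seed)
    entries: list[CohortEntry] = []
    for i in range(spec.n_subjects):
        sex = "M" if rng.random() < 0.5 else "F"
        tiv = rng.normal(
            spec.tiv_mean + (0.5 if sex == "M" else -0.5) * spec.sex_tiv_offset,
            spec.tiv_sd,
        )
        subject_scale = (
            1.0
            + spec.scale_tiv_slope * (tiv - spec.tiv_mean)
            + rng.normal(0.0, spec.scale_noise_sd)
        )
        if sex == "M":
            subject_scale *= 1.0 + spec.sex_effect
        for side in ("L", "R"):
            ear_scale = subject_scale * (
                1.0 + rng.normal(0.0, spec.side_noise_sd)
            )
            if side == "L":
                ear_scale *= 1.0 + spec.laterality_effect
            ear_scale = float(np.clip(ear_scale, 0.705, 1.295))
            params = replace(
                base,
                global_scale=ear_scale,
                side="left" if side == "L" else "right",
            )
            entries.append(
                CohortEntry(
                    subject=f"subj{i:03d}",
                    side=side,
                    sex=sex,
                    tiv_cm3=float(tiv),
                    params=params,
                    true_measures=true_measures(params, volumes=volumes),
                )
            )
    return entries


def cohort_to_table(entries: list[CohortEntry]):
    """Flatten a cohort into the (subject, side) keyed measure table."""
    import pandas as pd

    rows = []
    for e in entries:
        row = {"subject": e.subject, "side": e.side, "sex": e.sex,
               "tiv_cm3": e.tiv_cm3}
        row.update(e.true_measures)
        rows.append(row)
    return pd.DataFrame(rows)
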