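"""Landmark- and mesh-based morphometry of the bony labyrinth.

Implements the standard measurement protocol used for micro-CT comparison:
semicircular-canal heights, widths and internal lumen dimensions, the
derived canal radius, common crus length and widths, vestibule diameters,
cochlear length/width (chord through the modiolar axis within the fitted
basal-turn plane), cochlear heights (coronal and oblique), total inner-ear
length, per-region volumes, the simple geometric-model volumes used in older
literature, and the comparison table against published reference values.

All distance measures are Euclidean distances between two named landmarks;
where the historical protocol is only a visual guideline, the phantom ground
truth supplies the endpoint pair and this module does the arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import trimesh

from .core import LandmarkSet, SegmentationLabelmap
from .reid import PlaneFit, fit_plane
from .surfaces import mesh_volume

__all__ = [
    "MeasureReport",
    "GeometricModelParams",
    "DISTANCE_ENDPOINTS",
    "scc_radius",
    "landmark_distance_measures",
    "fit_basal_turn_plane",
    "cochlea_length_width",
    "cochlea_heights",
    "geometric_model_volumes",
    "region_volumes",
    "compare_to_literature",
    "measure_all",
    "literature_table",
    "round_half_away",
]

_CANALS = ("ant", "post", "lat")

#: distance measures defined as the Euclidean distance between two named
#: landmark endpoints ``<measure>_a`` / ``<measure>_b``
DISTANCE_ENDPOINTS: dict[str, tuple[str, str]] = {}
for _c in _CANALS:
    for _d in ("height", "width"):
        DISTANCE_ENDPOINTS[f"scc_{_c}_{_d}"] = (
            f"scc_{_c}_{_d}_a", f"scc_{_c}_{_d}_b")
    for _d in ("width", "height"):
        for _k in (1, 2, 3):
            m = f"scc_{_c}_internal_{_d}_{_k}"
            DISTANCE_ENDPOINTS[m] = (f"{m}_a", f"{m}_b")
for _m in (
    "common_crus_length", "common_crus_width_1", "common_crus_width_2",
    "common_crus_width_3", "vestibule_length", "vestibule_width",
    "inner_ear_length_total", "cochlea_height_coronal",
):
    DISTANCE_ENDPOINTS[_m] = (f"{_m}_a", f"{_m}_b")
DISTANCE_ENDPOINTS["cochlea_height_oblique"] = (
    "cochlea_nerve_foramen", "cochlea_apex")

_VOLUME_MEASURES = (
    "vol_ampulla_ant", "vol_ampulla_post", "vol_ampulla_lat",
    "vol_saccule", "vol_utricle", "vol_cochlea", "vol_inner_ear_total",
)

#: regions whose (summed) volume yields each volume measure
_MEASURE_REGIONS = {
    "vol_ampulla_ant": ("ampulla_ant",),
    "vol_ampulla_post": ("ampulla_post",),
    "vol_ampulla_lat": ("ampulla_lat",),
    "vol_saccule": ("saccule",),
    "vol_utricle": ("utricle",),
    "vol_cochlea": ("cochlea", "scala_vestibuli", "scala_tympani",
                    "cochlear_duct", "cupula"),
}

_KNOWN_REGIONS = frozenset(
    r for regions in _MEASURE_REGIONS.values() for r in regions
) | {"scc_ant", "scc_post", "scc_lat", "common_crus", "vestibule"}


class MeasureReport(dict):
    """Named scalar morphometric results: mm for distances, mm^3 for the
    ``vol_*`` entries."""

    @staticmethod
    def units(measure: str) -> str:
        return "mm^3" if measure.startswith("vol_") else "mm"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v, self.units(k)) for k, v in self.items()],
            columns=["measure", "value", "units"],
        )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (reporting convention of the result tables;
    numpy's default rounds half to even)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def scc_radius(height: float, width: float) -> float:
    """Semicircular-canal radius: 0.5 * (height + width) / 2."""
    if height < 0 or width < 0:
        raise ValueError("height and width must be non-negative")
    return 0.5 * (height + width) / 2.0


def landmark_distance_measures(landmarks: LandmarkSet
                               ) -> tuple[MeasureReport, list[str]]:
    """Evaluate every resolvable endpoint-pair distance measure.

    Returns the partial report plus the list of measures whose endpoints are
    missing (partial output by design: measurement sets need not carry the
    full protocol).  Canal radii are derived for every canal whose height
    and width both resolved.
    """
    report = MeasureReport()
    missing: list[str] = []
    for measure, (a, b) in DISTANCE_ENDPOINTS.items():
        if a in landmarks and b in landmarks:
            report[measure] = float(np.linalg.norm(landmarks[a] - landmarks[b]))
        else:
            missing.append(measure)
    for c in _CANALS:
        h, w = f"scc_{c}_height", f"scc_{c}_width"
        if h in report and w in report:
            report[f"scc_{c}_radius"] = scc_radius(report[h], report[w])
        else:
            missing.append(f"scc_{c}_radius")
    return report, missing


def fit_basal_turn_plane(points) -> PlaneFit:
    """Total-least-squares plane through the seven equidistant center-spiral
    points of the cochlear basal turn (same estimator as the Reid fit)."""
    if isinstance(points, LandmarkSet):
        names = [f"cochlea_basal_{k}" for k in range(1, 8)]
        missing = [n for n in names if n not in points]
        if missing:
            raise KeyError(f"missing basal-turn landmarks: {missing}")
        points = points.as_array(names)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape != (7, 3):
        raise ValueError(f"expected 7 x 3 points, got {points.shape}")
    return fit_plane(points)


def _project_to_plane(pts: np.ndarray, plane: PlaneFit):
    """In-plane 2-D coordinates of points projected along the plane normal."""
    n = plane.normal
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, n) * n
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    rel = np.atleast_2d(pts) - plane.point
    return np.stack([rel @ u, rel @ v], axis=1)


def cochlea_length_width(landmarks: LandmarkSet, basal_plane: PlaneFit,
                         axis_tolerance: float = 0.15
                         ) -> tuple[float, float]:
    """Cochlear length and width from the basal-turn contour.

    Length is the largest in-plane distance from the round window to a
    lateral-wall contour point such that the chord passes within
    ``axis_tolerance`` mm of the modiolar axis point.  Width is the longest
    chord through the modiolar axis perpendicular (in-plane) to the length
    line, intersected with the wall contour.
    """
    from shapely.geometry import LineString, Polygon

    for name in ("cochlea_round_window", "cochlea_modiolus"):
        if name not in landmarks:
            raise KeyError(f"missing landmark {name!r}")
    contour_names = sorted(
        n for n in landmarks.names() if n.startswith("cochlea_contour_")
    )
    if len(contour_names) < 8:
        raise ValueError("need a sampled lateral-wall contour "
                         "(landmarks 'cochlea_contour_*')")
    rw = _project_to_plane(landmarks["cochlea_round_window"], basal_plane)[0]
    mod = _project_to_plane(landmarks["cochlea_modiolus"], basal_plane)[0]
    contour = _project_to_plane(landmarks.as_array(contour_names), basal_plane)

    # chord constraint: perpendicular distance from the modiolar point to the
    # rw -> contour segment
    d = contour - rw
    lengths = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip(((mod - rw) @ d.T) / np.maximum(lengths**2, 1e-30), 0, 1)
    closest = rw + t[:, None] * d
    offsets = np.linalg.norm(mod - closest, axis=1)
    ok = offsets <= axis_tolerance
    if not ok.any():
        raise ValueError(
            "no round-window chord passes within "
            f"{axis_tolerance} mm of the modiolar axis "
            f"(minimum offset {offsets.min():.3f} mm)"
        )
    i_far = int(np.argmax(np.where(ok, lengths, -np.inf)))
    length = float(lengths[i_far])

    # width: chord through the modiolus, in-plane perpendicular to the length
    length_dir = d[i_far] / lengths[i_far]
    perp = np.array([-length_dir[1], length_dir[0]])
    span = lengths.max() * 2.0
    line = LineString([mod - span * perp, mod + span * perp])
    poly = Polygon(contour)
    inter = line.intersection(poly)
    if inter.is_empty:
        raise ValueError("width line misses the basal-turn contour")
    coords = np.array(
        [c for geom in getattr(inter, "geoms", [inter]) for c in geom.coords]
    )
    proj = coords @ perp
    width = float(proj.max() - proj.min())
    return length, width


def cochlea_heights(landmarks: LandmarkSet) -> tuple[float, float]:
    """(coronal, oblique) cochlear heights.

    Coronal: maximal vertical extent on a coronal cut (endpoint landmarks
    projected to a shared coronal line).  Oblique: free 3-D distance from the
    cochlear nerve foramen to the cochlear apex.
    """
    needed = ("cochlea_height_coronal_a", "cochlea_height_coronal_b",
              "cochlea_nerve_foramen", "cochlea_apex")
    missing = [n for n in needed if n not in landmarks]
    if missing:
        raise KeyError(f"missing cochlear landmarks: {missing}")
    a = landmarks["cochlea_height_coronal_a"]
    b = landmarks["cochlea_height_coronal_b"]
    coronal = float(abs(a[2] - b[2]))
    oblique = float(np.linalg.norm(
        landmarks["cochlea_apex"] - landmarks["cochlea_nerve_foramen"]))
    return coronal, oblique


@dataclass
class GeometricModelParams:
    """Simple geometric stand-ins used by early morphometric literature."""

    ampulla_sphere_diameter: float = 2.0
    saccule_hemisphere_diameter: float = 2.0
    utricle_diameter: float = 1.35
    utricle_length: float = 5.5
    cochlea_cone_diameter: float = 8.0
    cochlea_cone_height: float = 5.0

    def validate(self) -> None:
        if any(v <= 0 for v in self.__dict__.values()):
            raise ValueError("all geometric model parameters must be > 0")


def geometric_model_volumes(p: GeometricModelParams | None = None
                            ) -> MeasureReport:
    """Volumes of the geometric stand-ins (mm^3, reported at 1 d.p.):
    ampullae as spheres, saccule as a hemisphere, utricle as a cylinder
    (irregular oval of given diameter and length), cochlea as a cone."""
    p = p or GeometricModelParams()
    p.validate()
    sphere = 4.0 / 3.0 * math.pi * (p.ampulla_sphere_diameter / 2) ** 3
    hemi = 2.0 / 3.0 * math.pi * (p.saccule_hemisphere_diameter / 2) ** 3
    cyl = math.pi * (p.utricle_diameter / 2) ** 2 * p.utricle_length
    cone = math.pi * (p.cochlea_cone_diameter / 2) ** 2 * p.cochlea_cone_height / 3.0
    report = MeasureReport({
        "vol_ampulla_ant": sphere,
        "vol_ampulla_post": sphere,
        "vol_ampulla_lat": sphere,
        "vol_saccule": hemi,
        "vol_utricle": cyl,
        "vol_cochlea": cone,
    })
    return MeasureReport({k: round_half_away(v, 1) for k, v in report.items()})


def region_volumes(regions, iso_surface_mesh: trimesh.Trimesh | None = None
                   ) -> MeasureReport:
    """Per-region volumes from a labelmap or from region meshes (mm^3).

    ``regions`` is either a :class:`SegmentationLabelmap` (volume = voxel
    count x voxel volume) or a mapping region-name -> closed mesh (volume =
    divergence-theorem mesh volume).  ``vol_inner_ear_total`` is reported
    when the whole-labyrinth iso-surface mesh is supplied.
    """
    report = MeasureReport()
    if isinstance(regions, SegmentationLabelmap):
        unknown = [n for n in regions.names.values() if n not in _KNOWN_REGIONS]
        if unknown:
            raise KeyError(f"unknown region name(s): {unknown}")
        counts = {
            name: int(np.count_nonzero(regions.volume.values == label))
            for label, name in regions.names.items()
        }
        voxel = regions.volume.voxel_volume
        for measure, names in _MEASURE_REGIONS.items():
            present = [n for n in names if n in counts]
            if present:
                report[measure] = sum(counts[n] for n in present) * voxel
    else:
        unknown = [n for n in regions if n not in _KNOWN_REGIONS]
        if unknown:
            raise KeyError(f"unknown region name(s): {unknown}")
        for measure, names in _MEASURE_REGIONS.items():
            present = [n for n in names if n in regions]
            if present:
                report[measure] = float(
                    sum(mesh_volume(regions[n]) for n in present))
    if iso_surface_mesh is not None:
        report["vol_inner_ear_total"] = mesh_volume(iso_surface_mesh)
    return report


def literature_table() -> pd.DataFrame:
    """Published reference values (external constants, keyed by source)."""
    with resources.files("innerear.data").joinpath("literature.csv").open() as fh:
        return pd.read_csv(fh)


def compare_to_literature(report: MeasureReport,
                          lit: pd.DataFrame | None = None) -> pd.DataFrame:
    """Side-by-side comparison of measured values against literature means.

    Returns rows (measure, ours, lit, delta_mean, source) for every measure
    shared between the report and the reference table; ``delta_mean`` is
    |ours - lit| rounded to the table's printed precision.
    """
    lit = literature_table() if lit is None else lit
    rows = []
    for _, entry in lit.iterrows():
        m = entry["measure"]
        if m not in report:
            continue
        nd = int(entry["decimals"])
        ours = round_half_away(float(report[m]), nd)
        delta = round_half_away(abs(ours - float(entry["mean_lit"])), nd)
        rows.append((m, ours, float(entry["mean_lit"]), delta, entry["source"]))
    return pd.DataFrame(
        rows, columns=["measure", "ours", "lit", "delta_mean", "source"])


def measure_all(landmarks: LandmarkSet,
                axis_tolerance: float = 0.15) -> MeasureReport:
    """Full landmark-based measurement battery.

    Distance measures plus the derived canal radii, the contour-based
    cochlear length/width and both cochlear heights; measures whose
    landmarks are absent are simply omitted.
    """
    report, _ = landmark_distance_measures(landmarks)
    try:
        plane = fit_basal_turn_plane(landmarks)
        length, width = cochlea_length_width(landmarks, plane, axis_tolerance)
        report["cochlea_length"] = length
        report["cochlea_width"] = width
    except (KeyError, ValueError):
        pass
    try:
        coronal, oblique = cochlea_heights(landmarks)
        report["cochlea_height_coronal"] = coronal
        report["cochlea_height_oblique"] = oblique
    except KeyError:
        pass
    return report
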