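"""The Area Increase Ratio (AIR): statistic, grading, specimen pipeline, cohort summary.

A bone defect enlarges the apparent acetabular cavity, so the polygon drawn
over a defected sector is larger than the corresponding healthy one. The
defect entity of a sector is expressed as the percentage increase of the
defected sector area A_def over the native sector area A_nat::

    AIR = (A_def / A_nat - 1) * 100

and graded into four progressive categories:

    minimal 0–20 %, moderate >20–50 %, severe >50–100 %, massive >100 %.

The per-specimen pipeline mirrors the healthy hemipelvis onto the pathological
side using bilateral landmarks (ASIS, pubic tubercles), fits a sphere to the
native acetabular surface to locate the hip centre of rotation, builds the
three view planes and eight sectors on the native anatomy, overlays them on
the pathological side, and measures native and defected sector polygons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import (
    DegenerateInputError,
    Sphere,
    cross_section,
    fit_plane,
    fit_sphere,
    mirror_transform,
)
from .io import (
    SECTOR_LABELS,
    LandmarkName,
    LandmarkSet,
    SchemaError,
    Side,
    SpecimenRecord,
    SurfaceMesh,
)
from .sectors import (
    FirstHitProfile,
    RimProfile,
    build_frame,
    build_frontal_sectors,
    build_axial_sectors,
    build_sagittal_sectors,
    build_view_planes,
    defect_sector_polygon,
    frame_axes,
    native_sector_polygon,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GradingScheme",
    "DEFAULT_SCHEME",
    "REGION_OF_SECTOR",
    "AIRResult",
    "SpecimenReport",
    "CohortSummary",
    "AnalysisConfig",
    "compute_air",
    "grade",
    "select_acetabular_points",
    "fit_cor_sphere",
    "analyze_specimen",
    "summarize_cohort",
]

# Anatomical region of each sector (used for cohort cross-tabulations).
REGION_OF_SECTOR = {
    "PS-F": "posterior", "PS-A": "posterior",
    "SS-F": "superior", "SS-S": "superior",
    "AS-F": "anterior", "AS-A": "anterior",
    "MS-S": "medial", "MS-A": "medial",
}
REGIONS = ("posterior", "superior", "anterior", "medial")


@dataclass(frozen=True)
class GradingScheme:
    """Ordered severity categories with closed-above AIR upper bounds (%)."""

    categories: tuple = ("minimal", "moderate", "severe", "massive")
    upper_bounds: tuple = (20.0, 50.0, 100.0, math.inf)

    def __post_init__(self):
        if len(self.categories) != len(self.upper_bounds):
            raise ValueError("one upper bound per category required")
        bounds = list(self.upper_bounds)
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise ValueError("grading bounds must be strictly increasing")


DEFAULT_SCHEME = GradingScheme()


def compute_air(a_def: float, a_nat: float) -> float:
    """Area increase ratio in percent: ``(a_def / a_nat - 1) * 100``.

    ``a_nat`` must be positive and ``a_def`` non-negative.
    """
    if not a_nat > 0:
        raise ValueError(f"native sector area must be positive, got {a_nat}")
    if a_def < 0:
        raise ValueError(f"defected sector area must be non-negative, got {a_def}")
    return (a_def / a_nat - 1.0) * 100.0


def grade(air: float, scheme: GradingScheme = DEFAULT_SCHEME) -> str:
    """Severity category for an AIR value.

    Boundary values fall in the lower category (20 → minimal, 50 → moderate,
    100 → severe). Slightly negative AIR (measurement noise) is clamped to 0
    for grading; NaN is rejected.
    """
    if air is None or (isinstance(air, float) and math.isnan(air)) or np.isnan(air):
        raise ValueError("cannot grade NaN AIR")
    clamped = max(float(air), 0.0)
    for category, bound in zip(scheme.categories, scheme.upper_bounds):
        if clamped <= bound:
            return category
    return scheme.categories[-1]


@dataclass
class AIRResult:
    """Per-sector outcome: areas (mm²), AIR (%) and its grade."""

    sector: str
    a_nat: float
    a_def: float
    air: float
    grade: str
    unmeasurable: bool = False


@dataclass
class SpecimenReport:
    record: SpecimenRecord
    results: list
    rim_diameter_mm: float | None = None

    def __post_init__(self):
        labels = [r.sector for r in self.results]
        if sorted(labels) != sorted(SECTOR_LABELS):
            raise ValueError(f"a specimen report needs exactly one result per sector, got {labels}")

    def result(self, sector: str) -> AIRResult:
        return next(r for r in self.results if r.sector == sector)


@dataclass
class AnalysisConfig:
    """Tunable measurement parameters.

    delta_mm
        Distance from the mirrored native surface beyond which a pathological
        surface point counts as a defect border (default 2 mm).
    ray_step_deg
        Angular resolution of the polygon ray fan (default 1°); native and
        defected polygons share the same fan.
    min_coverage
        Minimum fraction of rays with pathological geometry before a sector is
        flagged unmeasurable (default 0.5).
    """

    delta_mm: float = 2.0
    ray_step_deg: float = 1.0
    min_coverage: float = 0.5
    scheme: GradingScheme = field(default_factory=GradingScheme)

    def __post_init__(self):
        if not self.delta_mm > 0:
            raise ValueError("delta_mm must be positive")
        if not (0.1 < self.ray_step_deg <= 10.0):
            raise ValueError("ray_step_deg must lie in (0.1, 10] degrees")


def select_acetabular_points(mesh: SurfaceMesh, rim_samples, lateral) -> np.ndarray:
    """Mesh vertices on the acetabular articular surface.

    Candidates lie in a radial shell around the rim-circle centre (0.35–1.3
    rim radii) on the medial side of the rim plane; this captures the cup
    while excluding distant cortex.
    """
    rim = np.asarray(rim_samples, dtype=float)
    if len(rim) < 8:
        raise DegenerateInputError("acetabular point selection needs at least 8 rim samples")
    center = rim.mean(axis=0)
    r0 = float(np.linalg.norm(rim - center, axis=1).mean())
    lateral = np.asarray(lateral, dtype=float)
    rel = mesh.vertices - center
    dist = np.linalg.norm(rel, axis=1)
    medial_side = rel @ lateral <= 0.15 * r0
    sel = (dist >= 0.35 * r0) & (dist <= 1.3 * r0) & medial_side
    pts = mesh.vertices[sel]
    if len(pts) < 20:
        raise DegenerateInputError(
            f"only {len(pts)} mesh vertices near the acetabulum; cannot fit the CoR sphere"
        )
    return pts


def fit_cor_sphere(mesh: SurfaceMesh, rim_samples, lateral) -> Sphere:
    """Centre-of-rotation sphere fitted to the acetabular surface (one trim-and-refit pass)."""
    pts = select_acetabular_points(mesh, rim_samples, lateral)
    sphere = fit_sphere(pts)
    resid = np.abs(np.linalg.norm(pts - sphere.center, axis=1) - sphere.radius)
    keep = resid < 0.2 * sphere.radius
    if keep.sum() >= 20 and keep.sum() < len(pts):
        sphere = fit_sphere(pts[keep])
    logger.info("CoR sphere: centre %s, radius %.2f mm (%d surface points)",
                np.round(sphere.center, 2), sphere.radius, int(keep.sum()))
    return sphere


def _section_measurement_points(mesh: SurfaceMesh, plane, tree: cKDTree, delta_mm: float):
    """Section contours of the pathological overlay: (defect candidates, all points) in-plane."""
    contours = cross_section(mesh, plane)
    if not contours:
        return np.empty((0, 2)), np.empty((0, 2))
    pts2 = np.vstack([c.points for c in contours])
    pts3 = plane.to_world(pts2)
    d, _ = tree.query(pts3, k=1)
    return pts2[d > delta_mm], pts2


def analyze_specimen(
    native_mesh: SurfaceMesh,
    pathological_mesh: SurfaceMesh,
    landmarks: dict,
    record: SpecimenRecord | None = None,
    config: AnalysisConfig | None = None,
) -> SpecimenReport:
    """Run the full three-phase measurement on one paired specimen.

    Phase 1 — mirroring: a reflection across the mid-sagittal plane is
    estimated from the bilateral ASIS / pubic-tubercle pairs and used to map
    the pathological hemipelvis onto the native side, so the native CoR, rim
    and reference lines can be overlaid on the pathological anatomy.

    Phase 2 — planes and sectors: the CoR comes from a least-squares sphere on
    the native acetabular surface; the frontal/sagittal/axial view planes and
    the eight sectors are built from the native landmarks.

    Phase 3 — analysis: per sector, the native polygon uses the acetabular rim
    (frontal) or the bone section contour (sagittal/axial) as its third side;
    the defected polygon extends that third side to the furthest borders of
    the bone defect (pathological surface points farther than ``delta_mm``
    from the mirrored native surface). AIR and its grade follow.
    """
    config = config or AnalysisConfig()
    record = record or SpecimenRecord(specimen_id="specimen")
    native_side = Side(native_mesh.side)
    if pathological_mesh.side == native_side:
        raise ValueError("native and pathological meshes must come from opposite sides")
    for s in (Side.LEFT, Side.RIGHT):
        if s not in landmarks:
            raise SchemaError(f"landmark file must cover both sides; missing {s.value}")

    # Phase 1 — mirroring (pathological geometry mapped onto the native side).
    pairs = [
        (landmarks[Side.LEFT].get(name), landmarks[Side.RIGHT].get(name))
        for name in (LandmarkName.ASIS, LandmarkName.PUBIC_TUBERCLE)
    ]
    mirror = mirror_transform(pairs)
    overlay = pathological_mesh.transformed(mirror)

    # Phase 2 — CoR, frame, planes, sectors (all on the native anatomy).
    ls_native = landmarks[native_side]
    if ls_native.n_rim_samples < 8:
        raise SchemaError("need at least 8 RIM_SAMPLE landmarks on the native side")
    rim = ls_native.rim_samples()
    _, _, lateral = frame_axes(landmarks, native_side)
    sphere = fit_cor_sphere(native_mesh, rim, lateral)
    frame = build_frame(landmarks, sphere.center, native_side)
    planes = build_view_planes(frame, rim)
    sectors = {}
    sectors.update(build_frontal_sectors(planes["frontal"], sphere.center, ls_native))
    sectors.update(build_sagittal_sectors(planes["sagittal"], sphere.center, ls_native))
    sectors.update(build_axial_sectors(planes["axial"], sphere.center, ls_native))

    # Phase 3 — per-plane third-side data.
    tree = cKDTree(native_mesh.vertices)
    rim_center = rim.mean(axis=0)
    rim_diameter = 2.0 * float(np.linalg.norm(rim - rim_center, axis=1).mean())

    profiles, defect_pts, presence_pts = {}, {}, {}
    frontal_plane = planes["frontal"].plane
    origin2 = frontal_plane.to_plane_coords(sphere.center)
    profiles["frontal"] = RimProfile(frontal_plane.to_plane_coords(rim), origin=origin2)
    d_all, _ = tree.query(overlay.vertices, k=1)
    proj = frontal_plane.to_plane_coords(overlay.vertices)
    defect_pts["frontal"] = proj[d_all > config.delta_mm]
    presence_pts["frontal"] = proj
    for name in ("sagittal", "axial"):
        plane = planes[name].plane
        contours_nat = cross_section(native_mesh, plane)
        profiles[name] = FirstHitProfile(contours_nat, origin=plane.to_plane_coords(sphere.center))
        defect_pts[name], presence_pts[name] = _section_measurement_points(
            overlay, plane, tree, config.delta_mm
        )

    results = []
    for label in SECTOR_LABELS:
        sector = sectors[label]
        plane_name = sector.view.name
        native_poly = native_sector_polygon(sector, profiles[plane_name], config.ray_step_deg)
        defect_poly = defect_sector_polygon(
            sector,
            profiles[plane_name],
            defect_pts[plane_name],
            presence_points2d=presence_pts[plane_name],
            step_deg=config.ray_step_deg,
            min_coverage=config.min_coverage,
        )
        a_nat, a_def = native_poly.area, defect_poly.area
        air = compute_air(a_def, a_nat)
        results.append(
            AIRResult(
                sector=label, a_nat=a_nat, a_def=a_def, air=air,
                grade=grade(air, config.scheme), unmeasurable=defect_poly.unmeasurable,
            )
        )
        logger.info("%s: A_nat=%.1f mm² A_def=%.1f mm² AIR=%+.2f%% (%s)",
                    label, a_nat, a_def, air, results[-1].grade)
    return SpecimenReport(record=record, results=results, rim_diameter_mm=rim_diameter)


@dataclass
class CohortSummary:
    """Grade and region counts across all analyzed sectors of a cohort."""

    n_specimens: int
    n_sectors: int
    grade_counts: dict
    region_grade_counts: dict  # region -> {grade: count}
    n_over_50: int
    air_min: float
    air_max: float

    def to_dict(self) -> dict:
        return {
            "n_specimens": self.n_specimens,
            "n_sectors": self.n_sectors,
            "grade_counts": dict(self.grade_counts),
            "region_grade_counts": {r: dict(g) for r, g in self.region_grade_counts.items()},
            "n_over_50_percent": self.n_over_50,
            "air_min": self.air_min,
            "air_max": self.air_max,
        }


def summarize_cohort(reports, scheme: GradingScheme = DEFAULT_SCHEME) -> CohortSummary:
    """Cohort-level tallies of labeled AIR values.

    Accepts a list of :class:`SpecimenReport` or a DataFrame with columns
    ``specimen``, ``sector``, ``air_percent``. Counts grades, the region ×
    grade cross-tabulation, sectors with AIR > 50 %, and the AIR range.
    """
    if isinstance(reports, pd.DataFrame):
        df = reports[["specimen", "sector", "air_percent"]].copy()
    else:
        rows = [
            {"specimen": rep.record.specimen_id, "sector": res.sector, "air_percent": res.air}
            for rep in reports
            for res in rep.results
        ]
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("summarize_cohort: no sector results")
    dup = df.duplicated(subset=["specimen", "sector"])
    if dup.any():
        bad = df.loc[dup, ["specimen", "sector"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate sector labels within a specimen: {bad}")
    unknown = set(df["sector"]) - set(SECTOR_LABELS)
    if unknown:
        raise ValueError(f"unknown sector labels: {sorted(unknown)}")

    grades = df["air_percent"].map(lambda a: grade(a, scheme))
    regions = df["sector"].map(REGION_OF_SECTOR)
    grade_counts = {c: int((grades == c).sum()) for c in scheme.categories}
    region_grade = {
        r: {c: int(((regions == r) & (grades == c)).sum()) for c in scheme.categories}
        for r in REGIONS
    }
    return CohortSummary(
        n_specimens=int(df["specimen"].nunique()),
        n_sectors=int(len(df)),
        grade_counts=grade_counts,
        region_grade_counts=region_grade,
        n_over_50=int((df["air_percent"] > 50.0).sum()),
        air_min=float(df["air_percent"].min()),
        air_max=float(df["air_percent"].max()),
    )
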