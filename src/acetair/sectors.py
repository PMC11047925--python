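"""Anatomical frame, view planes and acetabular sectors.

The acetabulum's four structural regions (posterior column, superior dome,
anterior column, medial wall) are represented as angular wedges around the
hip centre of rotation (CoR) on three mutually orthogonal view planes:

* **frontal** — the lateral view, defined by the acetabular rim plane; three
  sectors PS-F / SS-F / AS-F bounded by rays toward the acetabular-notch
  aspects, the ischiatic notch and the ASIS;
* **sagittal** — the section containing the superior–inferior rim chord;
  two sectors SS-S / MS-S bounded by the superior-rim ray, the ischiatic-notch
  ray and the caudal extension of the superior-rim ray;
* **axial** — the section containing the anterior–posterior rim chord; three
  sectors PS-A / MS-A / AS-A bounded by the posterior/anterior rim rays and
  rays toward the superior pubic ramus and the ischiatic spine.

Sector polygons use the acetabular rim (frontal) or the bone cross-section
contour (sagittal/axial) as their third side; on the pathological side the
furthest borders of the bone defect extend that third side radially.

In-plane axes are anatomical (anterior/superior/medial), so left- and
right-side specimens yield identical sector layouts without an explicit
re-mirroring step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    DegenerateInputError,
    GeometryError,
    Plane3,
    PlanarContour,
    fit_plane,
    polygon_area,
)
from .io import LandmarkName, LandmarkSet, SchemaError, Side

__all__ = [
    "DegenerateSectorError",
    "IncompleteRimError",
    "AnatomicalFrame",
    "ViewPlane",
    "ReferenceLine",
    "Sector",
    "SectorPolygon",
    "frame_axes",
    "build_frame",
    "build_view_planes",
    "build_frontal_sectors",
    "build_sagittal_sectors",
    "build_axial_sectors",
    "build_all_sectors",
    "RimProfile",
    "FirstHitProfile",
    "native_sector_polygon",
    "defect_sector_polygon",
]

TWO_PI = 2.0 * math.pi
_MIN_SEPARATION_RAD = math.radians(1.0)  # reference rays closer than 1° are degenerate


class DegenerateSectorError(GeometryError):
    """Reference rays coincide, are out of circular order, or a landmark projects onto the CoR."""


class IncompleteRimError(GeometryError):
    """The third-side curve does not span the sector's angular interval."""


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed anatomical directions anchored at the CoR.

    ``lateral`` points away from the body midline for the frame's side, so a
    left-side frame is the mirror image of a right-side one.
    """

    origin: np.ndarray
    anterior: np.ndarray
    superior: np.ndarray
    lateral: np.ndarray
    side: Side

    def __post_init__(self):
        for name in ("origin", "anterior", "superior", "lateral"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        for a, b in (("anterior", "superior"), ("anterior", "lateral"), ("superior", "lateral")):
            if abs(np.dot(getattr(self, a), getattr(self, b))) > 1e-9:
                raise GeometryError(f"frame axes {a} and {b} are not orthogonal")


@dataclass(frozen=True)
class ViewPlane:
    """One of the three named view planes; the plane's origin is the CoR."""

    name: str  # frontal | sagittal | axial
    plane: Plane3


@dataclass(frozen=True)
class ReferenceLine:
    """A sector-bounding ray from the in-plane CoR projection."""

    label: str
    angle: float  # radians, in the view plane's (u, v) polar frame
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(2))

    def direction(self) -> np.ndarray:
        return np.array([math.cos(self.angle), math.sin(self.angle)])


@dataclass(frozen=True)
class Sector:
    """An angular wedge in a view plane, swept counter-clockwise theta0 → theta1."""

    label: str
    view: ViewPlane
    line_start: ReferenceLine
    line_end: ReferenceLine
    theta0: float
    theta1: float

    @property
    def width(self) -> float:
        return (self.theta1 - self.theta0) % TWO_PI

    @property
    def origin(self) -> np.ndarray:
        return self.line_start.origin

    def contains_angle(self, theta) -> np.ndarray:
        rel = (np.asarray(theta, dtype=float) - self.theta0) % TWO_PI
        return rel <= self.width

    def fan(self, step_deg: float) -> np.ndarray:
        """Ray angles covering the wedge at ≤ ``step_deg`` spacing, endpoints included."""
        n = max(2, int(math.ceil(self.width / math.radians(step_deg))) + 1)
        return (self.theta0 + np.linspace(0.0, self.width, n)) % TWO_PI


@dataclass(frozen=True)
class SectorPolygon:
    """A measured sector polygon: CoR apex, two bounding-ray edges, radial third side."""

    label: str
    role: str  # native | pathological
    vertices: np.ndarray  # (N, 2) in view-plane coordinates
    source: str  # rim | defect_border
    theta: np.ndarray
    rho: np.ndarray
    unmeasurable: bool = False

    @property
    def area(self) -> float:
        return polygon_area(self.vertices)


# ---------------------------------------------------------------------------
# Frame and planes

def frame_axes(landmarks: dict, side: Side) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anatomical (anterior, superior, lateral) unit vectors from bilateral landmarks.

    The anterior direction is the normal of the anterior pelvic plane (both
    ASIS and both pubic tubercles); the superior direction is the mean
    ASIS→pubic-tubercle offset orthogonalized against it; lateral completes the
    triple, pointing away from the midline for ``side``.
    """
    side = Side(side)
    for s in (Side.LEFT, Side.RIGHT):
        if s not in landmarks:
            raise SchemaError(f"frame construction needs landmarks on side {s.value}")
        landmarks[s].require(LandmarkName.ASIS, LandmarkName.PUBIC_TUBERCLE)
    asis = {s: landmarks[s].get(LandmarkName.ASIS) for s in (Side.LEFT, Side.RIGHT)}
    pt = {s: landmarks[s].get(LandmarkName.PUBIC_TUBERCLE) for s in (Side.LEFT, Side.RIGHT)}

    sup0 = 0.5 * (asis[Side.LEFT] + asis[Side.RIGHT]) - 0.5 * (pt[Side.LEFT] + pt[Side.RIGHT])
    nrm = np.linalg.norm(sup0)
    if nrm < 1e-9:
        raise DegenerateInputError("ASIS and pubic tubercle centroids coincide")
    sup0 = sup0 / nrm

    app = fit_plane(np.stack([asis[Side.LEFT], asis[Side.RIGHT], pt[Side.LEFT], pt[Side.RIGHT]]))
    lat_right = asis[Side.RIGHT] - asis[Side.LEFT]
    handed = np.cross(sup0, lat_right)
    anterior = app.normal if np.dot(app.normal, handed) >= 0 else -app.normal

    superior = sup0 - np.dot(sup0, anterior) * anterior
    superior = superior / np.linalg.norm(superior)
    lateral = np.cross(anterior, superior)  # right-lateral
    if side is Side.LEFT:
        lateral = -lateral
    return anterior, superior, lateral


def build_frame(landmarks: dict, cor, side: Side) -> AnatomicalFrame:
    """Anatomical frame at the CoR; see :func:`frame_axes` for the directions."""
    anterior, superior, lateral = frame_axes(landmarks, side)
    return AnatomicalFrame(origin=cor, anterior=anterior, superior=superior, lateral=lateral, side=Side(side))


def build_view_planes(frame: AnatomicalFrame, rim_samples) -> dict:
    """The three orthogonal view planes, all passing through the CoR.

    Frontal orientation comes from the least-squares acetabular-rim plane
    (normal sign-aligned with the lateral axis); the sagittal plane contains
    the in-rim superior direction and the frontal normal; the axial plane
    contains the in-rim anterior direction and the frontal normal. In-plane
    (u, v) bases are anatomical:

    * frontal: u ≈ anterior, v ≈ superior (polar 0° = anterior, 90° = superior)
    * sagittal: u = lateral, v ≈ superior (0° = lateral, 180° = medial)
    * axial: u ≈ anterior, v = medial (0° = anterior, 90° = medial)
    """
    rim = np.asarray(rim_samples, dtype=float)
    if rim.ndim != 2 or len(rim) < 8:
        raise DegenerateInputError("build_view_planes: need at least 8 acetabular rim samples")
    rim_fit = fit_plane(rim, superior=frame.superior, anterior=frame.anterior)
    lat_dir = rim_fit.normal if np.dot(rim_fit.normal, frame.lateral) >= 0 else -rim_fit.normal

    sup_in = frame.superior - np.dot(frame.superior, lat_dir) * lat_dir
    nrm = np.linalg.norm(sup_in)
    if nrm < 1e-9:
        raise DegenerateInputError("rim plane normal parallel to the superior axis")
    e_sup = sup_in / nrm
    ant_in = frame.anterior - np.dot(frame.anterior, lat_dir) * lat_dir
    ant_in = ant_in - np.dot(ant_in, e_sup) * e_sup
    nrm = np.linalg.norm(ant_in)
    if nrm < 1e-9:
        raise DegenerateInputError("rim plane normal parallel to the anterior axis")
    e_ant = ant_in / nrm
    cor = frame.origin

    # Bases are anatomical for both sides; plane normals (u × v) may therefore
    # point medially on left-side specimens, which is irrelevant downstream.
    frontal = Plane3(origin=cor, u_axis=e_ant, v_axis=e_sup)
    sagittal = Plane3(origin=cor, u_axis=lat_dir, v_axis=e_sup)
    axial = Plane3(origin=cor, u_axis=e_ant, v_axis=-lat_dir)
    return {
        "frontal": ViewPlane("frontal", frontal),
        "sagittal": ViewPlane("sagittal", sagittal),
        "axial": ViewPlane("axial", axial),
    }


# ---------------------------------------------------------------------------
# Sector construction

def _ray_angle(view: ViewPlane, origin2: np.ndarray, point3, what: str) -> float:
    uv = view.plane.to_plane_coords(point3) - origin2
    r = float(np.hypot(uv[0], uv[1]))
    if r < 1e-6:
        raise DegenerateSectorError(f"{what} projects onto the CoR; reference direction undefined")
    return float(math.atan2(uv[1], uv[0]))


def _signed_step(a: float, b: float) -> float:
    """Wrapped angular step a→b in (−π, π]."""
    return (b - a + math.pi) % TWO_PI - math.pi


def _wedges(view: ViewPlane, origin2, rays: list[ReferenceLine], labels: list[str]) -> dict:
    """Sectors between consecutive reference rays.

    The rays must occur in consistent circular order (all steps with the same
    sign, each step larger than 1° and at most 180°); otherwise the published
    sector layout is not realizable and a :class:`DegenerateSectorError` is
    raised.
    """
    steps = [_signed_step(rays[i].angle, rays[i + 1].angle) for i in range(len(rays) - 1)]
    for line_a, line_b, step in zip(rays, rays[1:], steps):
        if abs(step) < _MIN_SEPARATION_RAD:
            raise DegenerateSectorError(
                f"reference lines {line_a.label} and {line_b.label} are within 1° of each other"
            )
    orient = math.copysign(1.0, steps[0])
    if any(math.copysign(1.0, s) != orient for s in steps):
        raise DegenerateSectorError(
            "reference lines are not in circular order: "
            + ", ".join(f"{r.label}@{math.degrees(r.angle) % 360:.1f}°" for r in rays)
        )
    if abs(sum(steps)) > TWO_PI - _MIN_SEPARATION_RAD:
        raise DegenerateSectorError("sector wedges would wrap past a full circle")
    sectors = {}
    for label, line_a, line_b in zip(labels, rays, rays[1:]):
        if orient > 0:
            theta0, theta1 = line_a.angle, line_b.angle
        else:
            theta0, theta1 = line_b.angle, line_a.angle
        sectors[label] = Sector(
            label=label, view=view, line_start=line_a, line_end=line_b,
            theta0=theta0 % TWO_PI, theta1=theta1 % TWO_PI,
        )
    return sectors


def build_frontal_sectors(view: ViewPlane, cor, landmarks: LandmarkSet) -> dict:
    """PS-F, SS-F, AS-F from the acetabular-notch, ischiatic-notch and ASIS rays.

    r1-F → anterior aspect of the acetabular notch, r2-F → ischiatic notch,
    r3-F → ASIS, r4-F → posterior aspect of the acetabular notch. PS-F lies
    between r1-F and r2-F, SS-F between r2-F and r3-F, AS-F between r3-F and
    r4-F; the remaining wedge (the acetabular notch itself) is not a sector.
    """
    landmarks.require(
        LandmarkName.ACETABULAR_NOTCH_ANTERIOR,
        LandmarkName.ACETABULAR_NOTCH_POSTERIOR,
        LandmarkName.ISCHIATIC_NOTCH,
        LandmarkName.ASIS,
    )
    origin2 = view.plane.to_plane_coords(cor)
    rays = [
        ReferenceLine("r1-F", _ray_angle(view, origin2, landmarks.get(LandmarkName.ACETABULAR_NOTCH_ANTERIOR), "acetabular notch (anterior)"), origin2),
        ReferenceLine("r2-F", _ray_angle(view, origin2, landmarks.get(LandmarkName.ISCHIATIC_NOTCH), "ischiatic notch"), origin2),
        ReferenceLine("r3-F", _ray_angle(view, origin2, landmarks.get(LandmarkName.ASIS), "ASIS"), origin2),
        ReferenceLine("r4-F", _ray_angle(view, origin2, landmarks.get(LandmarkName.ACETABULAR_NOTCH_POSTERIOR), "acetabular notch (posterior)"), origin2),
    ]
    return _wedges(view, origin2, rays, ["PS-F", "SS-F", "AS-F"])


def build_sagittal_sectors(view: ViewPlane, cor, landmarks: LandmarkSet) -> dict:
    """SS-S and MS-S from the superior-rim ray and the ischiatic-notch ray.

    r1-S points to the superior aspect of the acetabular rim, r2-S to the
    ischiatic-notch projection; MS-S is bounded by r2-S and the caudal
    extension of r1-S.
    """
    landmarks.require(LandmarkName.ISCHIATIC_NOTCH)
    if landmarks.n_rim_samples < 8:
        raise SchemaError("sagittal sectors need at least 8 acetabular rim samples")
    origin2 = view.plane.to_plane_coords(cor)
    rim2 = view.plane.to_plane_coords(landmarks.rim_samples()) - origin2
    sup_idx = int(np.argmax(rim2[:, 1]))  # v-axis is superior
    if np.hypot(*rim2[sup_idx]) < 1e-6:
        raise DegenerateSectorError("superior rim point projects onto the CoR")
    a1 = float(math.atan2(rim2[sup_idx, 1], rim2[sup_idx, 0]))
    rays = [
        ReferenceLine("r1-S", a1, origin2),
        ReferenceLine("r2-S", _ray_angle(view, origin2, landmarks.get(LandmarkName.ISCHIATIC_NOTCH), "ischiatic notch"), origin2),
        ReferenceLine("r1-S-caudal", a1 + math.pi, origin2),
    ]
    return _wedges(view, origin2, rays, ["SS-S", "MS-S"])


def build_axial_sectors(view: ViewPlane, cor, landmarks: LandmarkSet) -> dict:
    """PS-A, MS-A, AS-A from the rim extremes, pubic-ramus and ischiatic-spine rays.

    r1-A → posterior acetabular rim, r2-A → posterior part of the superior
    pubic ramus, r3-A → ischiatic spine, r4-A → anterior acetabular rim.
    """
    landmarks.require(LandmarkName.ISCHIATIC_SPINE, LandmarkName.SUPERIOR_PUBIC_RAMUS)
    if landmarks.n_rim_samples < 8:
        raise SchemaError("axial sectors need at least 8 acetabular rim samples")
    origin2 = view.plane.to_plane_coords(cor)
    rim2 = view.plane.to_plane_coords(landmarks.rim_samples()) - origin2
    post_idx = int(np.argmin(rim2[:, 0]))  # u-axis is anterior
    ant_idx = int(np.argmax(rim2[:, 0]))
    for idx, what in ((post_idx, "posterior rim"), (ant_idx, "anterior rim")):
        if np.hypot(*rim2[idx]) < 1e-6:
            raise DegenerateSectorError(f"{what} point projects onto the CoR")
    rays = [
        ReferenceLine("r1-A", float(math.atan2(rim2[post_idx, 1], rim2[post_idx, 0])), origin2),
        ReferenceLine("r2-A", _ray_angle(view, origin2, landmarks.get(LandmarkName.SUPERIOR_PUBIC_RAMUS), "superior pubic ramus"), origin2),
        ReferenceLine("r3-A", _ray_angle(view, origin2, landmarks.get(LandmarkName.ISCHIATIC_SPINE), "ischiatic spine"), origin2),
        ReferenceLine("r4-A", float(math.atan2(rim2[ant_idx, 1], rim2[ant_idx, 0])), origin2),
    ]
    return _wedges(view, origin2, rays, ["PS-A", "MS-A", "AS-A"])


def build_all_sectors(frame: AnatomicalFrame, landmarks: LandmarkSet) -> tuple[dict, dict]:
    """Planes plus all eight sectors for one specimen (3 frontal + 2 sagittal + 3 axial)."""
    planes = build_view_planes(frame, landmarks.rim_samples())
    sectors = {}
    sectors.update(build_frontal_sectors(planes["frontal"], frame.origin, landmarks))
    sectors.update(build_sagittal_sectors(planes["sagittal"], frame.origin, landmarks))
    sectors.update(build_axial_sectors(planes["axial"], frame.origin, landmarks))
    return planes, sectors


# ---------------------------------------------------------------------------
# Radial third-side profiles

class RimProfile:
    """Periodic linear interpolation ρ(θ) through in-plane rim points (e.g. projected rim samples)."""

    def __init__(self, points2d, origin=(0.0, 0.0)):
        pts = np.atleast_2d(np.asarray(points2d, dtype=float)) - np.asarray(origin, dtype=float)
        if len(pts) < 3:
            raise DegenerateInputError("RimProfile needs at least 3 points")
        theta = np.arctan2(pts[:, 1], pts[:, 0]) % TWO_PI
        rho = np.hypot(pts[:, 0], pts[:, 1])
        order = np.argsort(theta)
        self._theta = theta[order]
        self._rho = rho[order]

    def __call__(self, theta) -> np.ndarray:
        t = np.asarray(theta, dtype=float) % TWO_PI
        theta_ext = np.concatenate([self._theta, self._theta[:1] + TWO_PI])
        rho_ext = np.concatenate([self._rho, self._rho[:1]])
        t_shift = np.where(t < self._theta[0], t + TWO_PI, t)
        return np.interp(t_shift, theta_ext, rho_ext)


class FirstHitProfile:
    """ρ(θ) = distance from the origin to the first crossing of section contours.

    Rays are cast in-plane; the nearest positive intersection with any contour
    segment is the bone boundary (NaN where no segment is hit).
    """

    def __init__(self, contours: list[PlanarContour], origin=(0.0, 0.0)):
        origin = np.asarray(origin, dtype=float).reshape(2)
        segs_a, segs_b = [], []
        for contour in contours:
            pts = contour.points - origin
            if len(pts) < 2:
                continue
            a, b = pts[:-1], pts[1:]
            if contour.closed:
                a = np.vstack([a, pts[-1]])
                b = np.vstack([b, pts[0]])
            segs_a.append(a)
            segs_b.append(b)
        self._a = np.vstack(segs_a) if segs_a else np.empty((0, 2))
        self._b = np.vstack(segs_b) if segs_b else np.empty((0, 2))

    @property
    def n_segments(self) -> int:
        return len(self._a)

    def __call__(self, theta) -> np.ndarray:
        t = np.atleast_1d(np.asarray(theta, dtype=float))
        out = np.full(t.shape, np.nan)
        if len(self._a) == 0:
            return out if np.ndim(theta) else float(out[0])
        d = np.column_stack([np.cos(t), np.sin(t)])  # (R, 2)
        a, ab = self._a, self._b - self._a  # (S, 2)
        # Solve a + s*ab = r*d for each (ray, segment): cross products.
        cross_d_ab = d[:, None, 0] * ab[None, :, 1] - d[:, None, 1] * ab[None, :, 0]  # (R, S)
        cross_a_ab = a[None, :, 0] * ab[None, :, 1] - a[None, :, 1] * ab[None, :, 0]
        cross_a_d = d[:, None, 0] * a[None, :, 1] - d[:, None, 1] * a[None, :, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cross_a_ab / cross_d_ab
            s = -cross_a_d / cross_d_ab  # segment parameter of the hit
        # s tolerance is loose enough to catch rays passing through shared
        # segment endpoints that were split by the on-plane vertex nudge.
        valid = (np.abs(cross_d_ab) > 1e-15) & (s >= -1e-6) & (s <= 1 + 1e-6) & (r > 1e-9)
        r = np.where(valid, r, np.inf)
        best = r.min(axis=1)
        out = np.where(np.isfinite(best), best, np.nan)
        return out if np.ndim(theta) else float(out[0])


def _binned_furthest(points2d, origin, fan: np.ndarray, half_width: float):
    """Furthest point per angular bin around each fan angle.

    Returns (radius, angle) arrays over the fan bins (NaN where a bin holds no
    point). The angle is the furthest point's own polar angle, not the bin
    centre, so polygon vertices can sit on the actual border points.
    """
    rho = np.full(len(fan), np.nan)
    ang = np.full(len(fan), np.nan)
    pts = np.atleast_2d(np.asarray(points2d, dtype=float))
    if pts.size == 0:
        return rho, ang
    rel = pts - np.asarray(origin, dtype=float).reshape(2)
    radii = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    step = half_width * 2.0
    offset = (theta - fan[0] + half_width) % TWO_PI
    idx = np.floor(offset / step).astype(int)
    mask = (idx >= 0) & (idx < len(fan)) & (radii > 0)
    if not mask.any():
        return rho, ang
    idx, radii, offset = idx[mask], radii[mask], offset[mask]
    order = np.lexsort((radii, idx))  # furthest point of each bin sorts last
    last = np.flatnonzero(np.r_[idx[order][1:] != idx[order][:-1], True])
    sel = order[last]
    rho[idx[sel]] = radii[sel]
    ang[idx[sel]] = fan[0] - half_width + offset[sel]
    return rho, ang


def native_sector_polygon(sector: Sector, profile, step_deg: float = 1.0, role: str = "native") -> SectorPolygon:
    """Sector polygon with the rim / bone-boundary curve as the third side.

    The polygon is the CoR apex plus fan points at ≤ ``step_deg`` spacing whose
    radii come from ``profile`` (a callable θ → ρ). Raises
    :class:`IncompleteRimError` when the profile has gaps inside the sector.
    """
    fan = sector.fan(step_deg)
    rho = np.asarray(profile(fan), dtype=float)
    if np.isnan(rho).any() or (rho <= 0).any():
        n_bad = int(np.isnan(rho).sum() + (rho <= 0).sum())
        raise IncompleteRimError(
            f"sector {sector.label}: third-side curve missing along {n_bad}/{len(fan)} rays"
        )
    verts = np.vstack([sector.origin, sector.origin + rho[:, None] * np.column_stack([np.cos(fan), np.sin(fan)])])
    return SectorPolygon(label=sector.label, role=role, vertices=verts, source="rim", theta=fan, rho=rho)


def defect_sector_polygon(
    sector: Sector,
    native_profile,
    defect_points2d,
    presence_points2d=None,
    step_deg: float = 1.0,
    min_coverage: float = 0.5,
) -> SectorPolygon:
    """Pathological sector polygon using the furthest defect borders as the third side.

    Per angular bin of the ray fan, the furthest defect-border candidate (a
    pathological point markedly beyond the mirrored native surface) replaces
    the native third side when it lies beyond it; the polygon vertex is placed
    at that border point itself. Bins without candidates keep the native
    rim/boundary radius, so an intact side reproduces the native polygon
    exactly. The first and last vertices stay on the bounding reference lines.
    The polygon is flagged unmeasurable (not an error) when pathological
    geometry is present along fewer than ``min_coverage`` of the rays.
    """
    fan = sector.fan(step_deg)
    half = sector.width / (len(fan) - 1) / 2.0 if len(fan) > 1 else math.radians(step_deg) / 2.0
    rho_nat = np.asarray(native_profile(fan), dtype=float)
    if np.isnan(rho_nat).any() or (rho_nat <= 0).any():
        raise IncompleteRimError(f"sector {sector.label}: native third side incomplete")
    rho_def, ang_def = _binned_furthest(defect_points2d, sector.origin, fan, half)

    rho = rho_nat.copy()
    theta = fan.copy()
    better = np.isfinite(rho_def) & (rho_def > rho_nat)
    interior = better.copy()
    interior[0] = interior[-1] = False
    rho[interior] = rho_def[interior]
    theta[interior] = ang_def[interior]
    for end in (0, -1):  # bounding-line vertices keep the exact ray angle
        if better[end]:
            rho[end] = rho_def[end]

    unmeasurable = False
    if presence_points2d is not None:
        presence_rho, _ = _binned_furthest(presence_points2d, sector.origin, fan, half)
        coverage = float(np.isfinite(presence_rho).mean())
        unmeasurable = coverage < min_coverage
    verts = np.vstack([sector.origin, sector.origin + rho[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])])
    return SectorPolygon(
        label=sector.label, role="pathological", vertices=verts,
        source="defect_border", theta=theta, rho=rho, unmeasurable=unmeasurable,
    )
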