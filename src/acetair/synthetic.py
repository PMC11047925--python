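"""Synthetic paired hemipelvis specimens with analytically known ground truth.

The generator emulates the measurement situation of the real method — a
healthy (native) hemipelvis and a contralateral pathological one — with fully
controlled geometry:

* the acetabulum is a hemispherical cup of radius R (= rim diameter / 2)
  opening laterally, centred on the specimen's centre of rotation (CoR);
* bilateral ASIS / pubic-tubercle landmarks define an exact mid-sagittal
  mirror plane (x = 0) and an exactly axis-aligned anatomical frame;
* sector-defining landmarks (ischiatic notch, acetabular-notch aspects,
  ischiatic spine, superior pubic ramus, 12 rim samples) sit at parameterized
  positions chosen to realize the published sector layout;
* a bone defect is modelled as a radial enlargement of the cup surface: within
  a target sector's angular wedge (fraction ``coverage`` of the sector span)
  and an out-of-plane band around the sector's view plane, surface points are
  scaled by ``factor`` ≥ 1 away from the view plane's normal axis. This
  matches the area-increase semantics directly ("furthest border" moves from
  ρ = R to ρ = factor·R), so the own-sector ground-truth AIR approaches
  ``coverage · (factor² − 1) · 100``.

Ground truth is computed by an analytic oracle that never touches the
measurement pipeline: radial profiles ρ(θ) are built per view plane from the
ideal surface (dense sampling of the deformed patches, first principles only)
and sector areas follow by dense quadrature of ½∫ρ(θ)² dθ. The oracle also
captures cross-plane interactions (a large defect in one view plane can bulge
into another plane's profile), so ground truth and pipeline see the same
idealized world.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    PLANE_OF_SECTOR,
    SECTOR_LABELS,
    LandmarkName,
    LandmarkSet,
    Role,
    Side,
    SpecimenRecord,
    SurfaceMesh,
)

__all__ = [
    "DefectSpec",
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticSpecimen",
    "make_specimen",
    "make_cohort",
    "quadrature_sector_area",
    "AnalyticGeometry",
]

TWO_PI = 2.0 * math.pi

# Canonical bilateral landmark positions (mm); the midline is the plane x = 0.
_COR_OFFSET = 85.0
_ASIS = {"x": 120.0, "y": 70.0, "z": 80.0}
_PT = {"x": 30.0, "y": 70.0, "z": -25.0}

# Sector-landmark placement, relative to the CoR in units of the cup radius,
# expressed in anatomical components. Chosen so the reference rays realize the
# published wedge layout on all three view planes.
_AN_ANT_FRONTAL_DEG = 270.0   # inferior
_AN_POST_FRONTAL_DEG = 345.0  # infero-anterior
_IN_OFFSET = (-1.449, 0.389, 2.202)   # (anterior, superior, medial): frontal 165°, sagittal 170°
_IS_AXIAL_DEG = 70.0
_SPR_AXIAL_DEG = 135.0
_RIM_PHI_DEG = np.arange(0.0, 360.0, 30.0)  # 12 rim samples

# The cup surface continues a few degrees past the rim plane (as real bone
# does), so section contours extend beyond the sector-boundary rays and the
# first-hit third side stays defined at the boundaries even under noise.
_FLANGE_DEG = 4.0


@dataclass(frozen=True)
class DefectSpec:
    """One carved defect: radial enlargement of a sector's bone border.

    coverage
        Fraction of the sector's angular span affected, in (0, 1].
    position
        Where the affected wedge sits inside the span (0 = start, 1 = end of
        the counter-clockwise interval, 0.5 = centred).
    band_deg
        Out-of-plane angular half-width of the affected band around the
        sector's view plane.
    """

    sector: str
    factor: float
    coverage: float = 1.0
    position: float = 0.5
    band_deg: float = 12.0

    def __post_init__(self):
        if self.sector not in SECTOR_LABELS:
            raise ValueError(f"unknown sector label {self.sector!r}; expected one of {SECTOR_LABELS}")
        if not self.factor >= 1.0:
            raise ValueError("defect factor must be ≥ 1 (radial enlargement)")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")
        if not 0.0 <= self.position <= 1.0:
            raise ValueError("position must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one paired synthetic specimen.

    ``side`` is the pathological side; the native hemipelvis sits opposite.
    ``mesh_step_deg`` is the cup surface grid spacing — keep it at or below
    the analysis ray-fan step so every fan bin sees mesh samples.
    """

    cup_radius_mm: float = 28.0
    side: Side = Side.RIGHT
    defects: tuple = ()
    mesh_step_deg: float = 1.0
    noise_sigma_mm: float = 0.0
    seed: int = 0
    specimen_id: str = "synthetic"
    paprosky_type: str | None = None

    def __post_init__(self):
        if not self.cup_radius_mm > 0:
            raise ValueError("cup radius must be positive")
        object.__setattr__(self, "side", Side(self.side))
        object.__setattr__(self, "defects", tuple(self.defects))


@dataclass
class GroundTruth:
    """Per-sector true native/defected areas (mm²) and true AIR (%)."""

    a_nat: dict
    a_def: dict
    air: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sector": list(SECTOR_LABELS),
                "a_nat_mm2": [self.a_nat[s] for s in SECTOR_LABELS],
                "a_def_mm2": [self.a_def[s] for s in SECTOR_LABELS],
                "air_percent": [self.air[s] for s in SECTOR_LABELS],
            }
        )


@dataclass
class SyntheticSpecimen:
    spec: SyntheticSpec
    record: SpecimenRecord
    native_mesh: SurfaceMesh
    pathological_mesh: SurfaceMesh
    landmarks: dict  # {Side: LandmarkSet}
    ground_truth: GroundTruth


class _Anatomy:
    """Canonical single-side geometry: axes, CoR, landmarks, plane bases, sector spans."""

    def __init__(self, cup_radius: float, side: Side):
        self.R = float(cup_radius)
        self.side = Side(side)
        s = 1.0 if self.side is Side.RIGHT else -1.0
        self.lat = np.array([s, 0.0, 0.0])
        self.ant = np.array([0.0, 1.0, 0.0])
        self.sup = np.array([0.0, 0.0, 1.0])
        self.med = -self.lat
        self.cor = np.array([s * _COR_OFFSET, 0.0, 0.0])

    # -- landmarks ---------------------------------------------------------
    def landmark_points(self) -> dict:
        R = self.R
        pts = {
            LandmarkName.ASIS.value: np.array([np.sign(self.lat[0]) * _ASIS["x"], _ASIS["y"], _ASIS["z"]]),
            LandmarkName.PUBIC_TUBERCLE.value: np.array([np.sign(self.lat[0]) * _PT["x"], _PT["y"], _PT["z"]]),
        }
        for name, deg, radius, medial in (
            (LandmarkName.ACETABULAR_NOTCH_ANTERIOR.value, _AN_ANT_FRONTAL_DEG, 1.2, 0.3),
            (LandmarkName.ACETABULAR_NOTCH_POSTERIOR.value, _AN_POST_FRONTAL_DEG, 1.2, 0.2),
        ):
            a = math.radians(deg)
            pts[name] = self.cor + radius * R * (math.cos(a) * self.ant + math.sin(a) * self.sup) + medial * R * self.med
        pts[LandmarkName.ISCHIATIC_NOTCH.value] = self.cor + R * (
            _IN_OFFSET[0] * self.ant + _IN_OFFSET[1] * self.sup + _IN_OFFSET[2] * self.med
        )
        a_is = math.radians(_IS_AXIAL_DEG)
        pts[LandmarkName.ISCHIATIC_SPINE.value] = self.cor + 1.5 * R * (
            math.cos(a_is) * self.ant + math.sin(a_is) * self.med
        ) - 0.8 * R * self.sup
        a_spr = math.radians(_SPR_AXIAL_DEG)
        pts[LandmarkName.SUPERIOR_PUBIC_RAMUS.value] = self.cor + 1.5 * R * (
            math.cos(a_spr) * self.ant + math.sin(a_spr) * self.med
        ) - 0.6 * R * self.sup
        for i, phi in enumerate(_RIM_PHI_DEG, start=1):
            a = math.radians(phi)
            pts[f"RIM_SAMPLE_{i}"] = self.cor + R * (math.cos(a) * self.ant + math.sin(a) * self.sup)
        return pts

    def landmark_set(self) -> LandmarkSet:
        return LandmarkSet(side=self.side, points=self.landmark_points())

    # -- view planes -------------------------------------------------------
    def plane_basis(self, plane: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u, v, n) of a view plane: polar angles are measured as atan2(·v, ·u)."""
        if plane == "frontal":
            return self.ant, self.sup, self.lat
        if plane == "sagittal":
            return self.lat, self.sup, self.ant
        if plane == "axial":
            return self.ant, self.med, self.sup
        raise ValueError(f"unknown plane {plane!r}")

    # -- sector layout -----------------------------------------------------
    def _angle_in(self, plane: str, point: np.ndarray) -> float:
        u, v, _ = self.plane_basis(plane)
        rel = point - self.cor
        return math.atan2(float(rel @ v), float(rel @ u)) % TWO_PI

    def sector_spans(self) -> dict:
        """{label: (theta0, width)} — counter-clockwise wedges in each plane's polar frame."""
        lm = self.landmark_points()
        f = {
            "r1": self._angle_in("frontal", lm[LandmarkName.ACETABULAR_NOTCH_ANTERIOR.value]),
            "r2": self._angle_in("frontal", lm[LandmarkName.ISCHIATIC_NOTCH.value]),
            "r3": self._angle_in("frontal", lm[LandmarkName.ASIS.value]),
            "r4": self._angle_in("frontal", lm[LandmarkName.ACETABULAR_NOTCH_POSTERIOR.value]),
        }
        sag_r1 = math.pi / 2.0  # superior rim point
        sag_r2 = self._angle_in("sagittal", lm[LandmarkName.ISCHIATIC_NOTCH.value])
        ax = {
            "r1": math.pi,  # posterior rim point
            "r2": self._angle_in("axial", lm[LandmarkName.SUPERIOR_PUBIC_RAMUS.value]),
            "r3": self._angle_in("axial", lm[LandmarkName.ISCHIATIC_SPINE.value]),
            "r4": 0.0,  # anterior rim point
        }

        def ccw(a, b):
            return (b - a) % TWO_PI

        return {
            # frontal rays run clockwise r1 → r2 → r3 → r4
            "PS-F": (f["r2"], ccw(f["r2"], f["r1"])),
            "SS-F": (f["r3"], ccw(f["r3"], f["r2"])),
            "AS-F": (f["r4"], ccw(f["r4"], f["r3"])),
            # sagittal rays run counter-clockwise r1 → r2 → caudal extension
            "SS-S": (sag_r1, ccw(sag_r1, sag_r2)),
            "MS-S": (sag_r2, ccw(sag_r2, sag_r1 + math.pi)),
            # axial rays run clockwise r1 → r2 → r3 → r4
            "PS-A": (ax["r2"], ccw(ax["r2"], ax["r1"])),
            "MS-A": (ax["r3"], ccw(ax["r3"], ax["r2"])),
            "AS-A": (ax["r4"], ccw(ax["r4"], ax["r3"])),
        }


@dataclass(frozen=True)
class _Region:
    """A resolved defect region: wedge in a plane's polar frame plus out-of-plane band."""

    plane: str
    u: np.ndarray
    v: np.ndarray
    n: np.ndarray
    wedge_start: float
    wedge_width: float
    band_mm: float
    factor: float

    def contains(self, rel_points: np.ndarray) -> np.ndarray:
        """Membership of points given relative to the CoR, shape (N, 3)."""
        o = rel_points @ self.n
        theta = np.arctan2(rel_points @ self.v, rel_points @ self.u)
        in_wedge = (theta - self.wedge_start) % TWO_PI <= self.wedge_width
        return (np.abs(o) <= self.band_mm) & in_wedge

    def deform(self, rel_points: np.ndarray) -> np.ndarray:
        """Scale the in-plane component by ``factor`` (relative coordinates)."""
        o = (rel_points @ self.n)[:, None] * self.n
        return self.factor * (rel_points - o) + o


def _resolve_regions(anatomy: _Anatomy, defects) -> list[_Region]:
    spans = anatomy.sector_spans()
    regions = []
    for d in defects:
        plane = PLANE_OF_SECTOR[d.sector]
        u, v, n = anatomy.plane_basis(plane)
        theta0, width = spans[d.sector]
        wwidth = d.coverage * width
        start = theta0 + d.position * (width - wwidth)
        regions.append(
            _Region(
                plane=plane, u=u, v=v, n=n,
                wedge_start=start % TWO_PI, wedge_width=wwidth,
                band_mm=anatomy.R * math.sin(math.radians(d.band_deg)),
                factor=d.factor,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# Cup mesh

def _cup_mesh(anatomy: _Anatomy, step_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Hemispherical cup opening laterally: pole at the medial wall, rim ring at the opening."""
    R, cor = anatomy.R, anatomy.cor
    alpha_max = 90.0 + _FLANGE_DEG
    n_alpha = max(8, int(round(alpha_max / step_deg)))
    n_phi = max(16, int(round(360.0 / step_deg)))
    alphas = np.linspace(0.0, math.radians(alpha_max), n_alpha + 1)[1:]  # pole handled separately
    phis = np.arange(n_phi) * (TWO_PI / n_phi)
    ca, sa = np.cos(alphas), np.sin(alphas)
    cp, sp = np.cos(phis), np.sin(phis)
    # direction = -cos(alpha)*lat + sin(alpha)*(cos(phi)*ant + sin(phi)*sup)
    dirs = (
        -ca[:, None, None] * anatomy.lat
        + sa[:, None, None] * (cp[:, None] * anatomy.ant + sp[:, None] * anatomy.sup)[None, :, :]
    )
    ring_vertices = (cor + R * dirs).reshape(-1, 3)
    pole = cor - R * anatomy.lat
    vertices = np.vstack([pole, ring_vertices])

    faces = []
    for j in range(n_phi):  # pole fan
        faces.append([0, 1 + j, 1 + (j + 1) % n_phi])
    for i in range(len(alphas) - 1):
        row0, row1 = 1 + i * n_phi, 1 + (i + 1) * n_phi
        j = np.arange(n_phi)
        jn = (j + 1) % n_phi
        quad_a = np.column_stack([row0 + j, row1 + j, row1 + jn])
        quad_b = np.column_stack([row0 + j, row1 + jn, row0 + jn])
        faces.extend(quad_a.tolist())
        faces.extend(quad_b.tolist())
    return vertices, np.asarray(faces, dtype=np.int64)


def _apply_defects(vertices: np.ndarray, cor: np.ndarray, regions: list[_Region]) -> np.ndarray:
    rel = vertices - cor
    hit_count = np.zeros(len(vertices), dtype=int)
    out = rel.copy()
    for region in regions:
        mask = region.contains(rel)
        hit_count += mask
        out[mask] = region.deform(rel[mask])
    if (hit_count > 1).any():
        raise ValueError(
            "defect regions overlap; choose disjoint wedges/bands so the carved "
            "geometry (and its ground truth) stays well defined"
        )
    return cor + out


# ---------------------------------------------------------------------------
# Analytic ground-truth oracle

def quadrature_sector_area(rho_fn, theta0: float, theta1: float, step_deg: float = 0.01) -> float:
    """Sector area by dense quadrature ½∫ρ(θ)² dθ (trapezoidal rule).

    ``rho_fn`` maps angles (radians, array) to radii; ``theta1`` may exceed
    2π to express wrap-around intervals. Used only by tests and the synthetic
    ground truth, never by the measurement pipeline.
    """
    width = theta1 - theta0
    if width <= 0:
        raise ValueError("theta1 must exceed theta0")
    n = max(3, int(math.ceil(width / math.radians(step_deg))) + 1)
    theta = theta0 + np.linspace(0.0, width, n)
    rho = np.asarray(rho_fn(theta), dtype=float)
    return float(np.trapezoid(0.5 * rho**2, theta))


class AnalyticGeometry:
    """Idealized (mesh-free) model of one defected cup, for ground-truth areas.

    Per view plane a dense radial profile ρ(θ) is assembled: the native
    boundary contributes ρ = R everywhere; each deformed patch contributes its
    furthest borders, via its exact section curve (section planes) or its
    dense-sampled projection (frontal plane). Sector areas integrate ½ρ².
    """

    BIN_DEG = 0.05

    def __init__(self, anatomy: _Anatomy, regions: list[_Region]):
        self.anatomy = anatomy
        self.regions = regions
        self._profiles: dict[str, np.ndarray] = {}

    def _n_bins(self) -> int:
        return int(round(360.0 / self.BIN_DEG))

    def _bin_max(self, profile: np.ndarray, theta: np.ndarray, rho: np.ndarray) -> None:
        idx = np.floor((theta % TWO_PI) / math.radians(self.BIN_DEG)).astype(int) % len(profile)
        np.maximum.at(profile, idx, rho)

    def profile(self, plane: str) -> np.ndarray:
        """ρ(θ) over the full circle at BIN_DEG resolution for one view plane."""
        if plane in self._profiles:
            return self._profiles[plane]
        an = self.anatomy
        R = an.R
        prof = np.full(self._n_bins(), R)
        u, v, n = an.plane_basis(plane)
        for region in self.regions:
            if plane == "frontal":
                theta, rho = self._projected_patch(region)
            else:
                theta, rho = self._section_curve(region, u, v)
            if len(theta):
                self._bin_max(prof, theta, rho)
        self._profiles[plane] = prof
        return prof

    def _section_curve(self, region: _Region, u, v) -> tuple[np.ndarray, np.ndarray]:
        """Deformed-patch boundary inside a section plane (exact: the deformation
        preserves each view plane because plane normals are mutually orthogonal)."""
        an = self.anatomy
        tau = np.arange(0.0, TWO_PI, math.radians(0.005))
        pts = an.R * (np.cos(tau)[:, None] * u + np.sin(tau)[:, None] * v)
        lat_max = an.R * math.sin(math.radians(_FLANGE_DEG)) + 1e-9
        mask = (pts @ an.lat <= lat_max) & region.contains(pts)
        if not mask.any():
            return np.empty(0), np.empty(0)
        moved = region.deform(pts[mask])
        return np.arctan2(moved @ v, moved @ u), np.linalg.norm(moved, axis=1)

    def _projected_patch(self, region: _Region) -> tuple[np.ndarray, np.ndarray]:
        """Frontal-view footprint of a deformed patch: dense (wedge × band) sampling.

        Near the projection axis the projected angle is governed by the
        out-of-plane coordinate, so the band is sampled as densely as the
        wedge (both well below the profile bin width).
        """
        an = self.anatomy
        n_tau = max(8, int(math.ceil(math.degrees(region.wedge_width) / 0.02)))
        tau = region.wedge_start + np.linspace(0.0, region.wedge_width, n_tau)
        o = np.linspace(-region.band_mm, region.band_mm, 601)
        rho_ip = np.sqrt(np.maximum(an.R**2 - o**2, 0.0))
        # points p = o*n + rho_ip*(cos tau * u + sin tau * v), all (tau, o) combos
        inplane_dir = np.cos(tau)[:, None] * region.u + np.sin(tau)[:, None] * region.v  # (T, 3)
        pts = o[None, :, None] * region.n + rho_ip[None, :, None] * inplane_dir[:, None, :]  # (T, O, 3)
        pts = pts.reshape(-1, 3)
        mask = pts @ an.lat <= an.R * math.sin(math.radians(_FLANGE_DEG)) + 1e-9
        pts = pts[mask]
        if not len(pts):
            return np.empty(0), np.empty(0)
        moved = region.deform(pts)
        a_c, s_c = moved @ an.ant, moved @ an.sup
        return np.arctan2(s_c, a_c), np.hypot(a_c, s_c)

    def sector_area(self, label: str, defected: bool = True) -> float:
        """Ground-truth sector area (mm²): native (ρ = R) or defected profile.

        The defected area is the closed-form native area plus the binned
        quadrature of ½(ρ² − R²), so intact sectors are exactly native.
        """
        theta0, width = self.anatomy.sector_spans()[label]
        native = 0.5 * self.anatomy.R**2 * width
        if not defected:
            return native
        prof = self.profile(PLANE_OF_SECTOR[label])
        bin_rad = math.radians(self.BIN_DEG)
        centers = (np.arange(len(prof)) + 0.5) * bin_rad
        in_span = (centers - theta0) % TWO_PI <= width
        increment = 0.5 * np.sum(prof[in_span] ** 2 - self.anatomy.R**2) * bin_rad
        return float(native + max(increment, 0.0))


# ---------------------------------------------------------------------------
# Specimen and cohort construction

def make_specimen(spec: SyntheticSpec) -> SyntheticSpecimen:
    """Build one paired specimen: native cup, mirrored-and-carved pathological cup,
    bilateral landmarks, and oracle ground truth."""
    native_side = spec.side.opposite
    native_anatomy = _Anatomy(spec.cup_radius_mm, native_side)
    path_anatomy = _Anatomy(spec.cup_radius_mm, spec.side)
    regions = _resolve_regions(path_anatomy, spec.defects)

    nat_vertices, faces = _cup_mesh(native_anatomy, spec.mesh_step_deg)
    path_vertices, _ = _cup_mesh(path_anatomy, spec.mesh_step_deg)
    path_vertices = _apply_defects(path_vertices, path_anatomy.cor, regions)

    if spec.noise_sigma_mm > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 17]))
        for verts, cor in ((nat_vertices, native_anatomy.cor), (path_vertices, path_anatomy.cor)):
            rel = verts - cor
            radial = rel / np.linalg.norm(rel, axis=1, keepdims=True)
            verts += spec.noise_sigma_mm * rng.standard_normal((len(verts), 1)) * radial

    native_mesh = SurfaceMesh(vertices=nat_vertices, faces=faces, side=native_side, role=Role.NATIVE)
    path_mesh = SurfaceMesh(vertices=path_vertices, faces=faces.copy(), side=spec.side, role=Role.PATHOLOGICAL)
    landmarks = {
        native_side: native_anatomy.landmark_set(),
        spec.side: path_anatomy.landmark_set(),
    }

    oracle = AnalyticGeometry(path_anatomy, regions)
    a_nat = {s: oracle.sector_area(s, defected=False) for s in SECTOR_LABELS}
    a_def = {s: oracle.sector_area(s, defected=True) for s in SECTOR_LABELS}
    air = {s: (a_def[s] / a_nat[s] - 1.0) * 100.0 for s in SECTOR_LABELS}
    record = SpecimenRecord(
        specimen_id=spec.specimen_id,
        side=spec.side,
        diagnosis="synthetic defect" if spec.defects else "synthetic intact",
        paprosky_type=spec.paprosky_type,
        rim_diameter_mm=2.0 * spec.cup_radius_mm,
    )
    return SyntheticSpecimen(
        spec=spec,
        record=record,
        native_mesh=native_mesh,
        pathological_mesh=path_mesh,
        landmarks=landmarks,
        ground_truth=GroundTruth(a_nat=a_nat, a_def=a_def, air=air),
    )


# Six presets mimicking a small revision-arthroplasty cohort: rim diameters in
# the 52–66 mm range, one intact specimen, medial-dominant and multi-sector
# patterns, and defects spanning all four severity grades. Wedge positions keep
# defects clear of the view-plane crossing directions where practical.
_COHORT_PRESETS: tuple = (
    dict(diameter=66.0, side=Side.RIGHT, paprosky="IIC", defects=(
        DefectSpec("MS-S", factor=1.45, coverage=0.70, position=0.78),
        DefectSpec("MS-A", factor=1.60, coverage=0.45, position=0.95),
        DefectSpec("SS-S", factor=1.30, coverage=0.50),
    )),
    dict(diameter=56.0, side=Side.RIGHT, paprosky="IIIB", defects=(
        DefectSpec("SS-S", factor=1.80, coverage=0.90),
        DefectSpec("MS-A", factor=1.75, coverage=0.58, position=0.85),
        DefectSpec("PS-F", factor=1.30, coverage=0.60),
    )),
    dict(diameter=56.0, side=Side.LEFT, paprosky="I", defects=()),
    dict(diameter=52.0, side=Side.LEFT, paprosky="IIA", defects=(
        DefectSpec("AS-A", factor=1.12, coverage=0.50),
        DefectSpec("PS-A", factor=1.40, coverage=0.80, position=0.40),
        DefectSpec("SS-F", factor=1.25, coverage=0.60, position=0.95),
    )),
    dict(diameter=54.0, side=Side.RIGHT, paprosky="IIIA", defects=(
        DefectSpec("AS-F", factor=1.50, coverage=0.45, position=0.70),
        DefectSpec("MS-S", factor=2.00, coverage=0.75, position=0.60),
        DefectSpec("PS-A", factor=1.35, coverage=0.50),
    )),
    dict(diameter=58.0, side=Side.RIGHT, paprosky="IIIB", defects=(
        DefectSpec("PS-F", factor=1.45, coverage=0.80, position=0.857),
        DefectSpec("SS-S", factor=1.50, coverage=0.35),
        DefectSpec("AS-A", factor=1.30, coverage=0.90, position=0.60),
    )),
)


def make_cohort(n: int = 6, seed: int = 0, noise_sigma_mm: float = 0.0,
                mesh_step_deg: float = 1.0) -> list[SyntheticSpecimen]:
    """A deterministic cohort of paired specimens spanning all grades and regions.

    The first six specimens follow fixed presets (including one intact,
    no-defect specimen and several multi-sector ones); beyond six, presets are
    recycled with seed-jittered rim diameters.
    """
    if n < 1:
        raise ValueError("cohort size must be ≥ 1")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    specimens = []
    for i in range(n):
        preset = _COHORT_PRESETS[i % len(_COHORT_PRESETS)]
        diameter = preset["diameter"]
        if i >= len(_COHORT_PRESETS):
            diameter = float(np.clip(diameter + rng.uniform(-3.0, 3.0), 46.0, 70.0))
        spec = SyntheticSpec(
            cup_radius_mm=diameter / 2.0,
            side=preset["side"],
            defects=preset["defects"],
            mesh_step_deg=mesh_step_deg,
            noise_sigma_mm=noise_sigma_mm,
            seed=(seed + i) & 0x7FFFFFFF,
            specimen_id=str(i + 1),
            paprosky_type=preset["paprosky"],
        )
        specimens.append(make_specimen(spec))
    return specimens
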