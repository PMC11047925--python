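"""Anatomical frame, view planes, sector wedges and sector polygons."""

import math

import numpy as np
import pytest

from acetair.geometry import Plane3, RigidTransform
from acetair.io import LandmarkName, LandmarkSet, SchemaError, Side
from acetair.sectors import (
    DegenerateSectorError,
    FirstHitProfile,
    IncompleteRimError,
    ReferenceLine,
    RimProfile,
    Sector,
    SectorPolygon,
    ViewPlane,
    build_all_sectors,
    build_frame,
    build_frontal_sectors,
    build_sagittal_sectors,
    build_view_planes,
    defect_sector_polygon,
    native_sector_polygon,
)
from acetair.synthetic import quadrature_sector_area

COR = np.array([85.0, 0.0, 0.0])


def ideal_landmarks():
    """Bilateral ASIS/pubic tubercles of an upright pelvis aligned to global axes."""
    def mk(side, sx):
        return LandmarkSet(side=side, points={
            "ASIS": [sx * 120.0, 70.0, 80.0],
            "PUBIC_TUBERCLE": [sx * 30.0, 70.0, -25.0],
        })
    return {Side.RIGHT: mk(Side.RIGHT, 1.0), Side.LEFT: mk(Side.LEFT, -1.0)}


def frontal_view(cor=COR):
    plane = Plane3(origin=cor, u_axis=(0, 1, 0), v_axis=(0, 0, 1))  # u=anterior, v=superior
    return ViewPlane("frontal", plane)


def landmark_at(view, cor, angle_deg, radius=35.0, off_plane=5.0):
    """3D point whose in-plane projection sits at the requested polar angle."""
    a = math.radians(angle_deg)
    return (
        np.asarray(cor)
        + radius * (math.cos(a) * view.plane.u_axis + math.sin(a) * view.plane.v_axis)
        + off_plane * view.plane.normal
    )


class TestFrame:
    def test_ideal_pelvis_gives_global_axes(self):
        frame = build_frame(ideal_landmarks(), COR, Side.RIGHT)
        assert np.allclose(frame.anterior, [0, 1, 0], atol=1e-6)
        assert np.allclose(frame.superior, [0, 0, 1], atol=1e-6)
        assert np.allclose(frame.lateral, [1, 0, 0], atol=1e-6)

    def test_left_lateral_is_mirror_of_right(self):
        lms = ideal_landmarks()
        right = build_frame(lms, COR, Side.RIGHT)
        left = build_frame(lms, -COR, Side.LEFT)
        assert np.allclose(left.lateral, -right.lateral, atol=1e-9)
        assert np.allclose(left.anterior, right.anterior, atol=1e-9)
        assert np.allclose(left.superior, right.superior, atol=1e-9)

    def test_axes_orthonormal_for_randomized_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            lms = ideal_landmarks()
            for side in lms:
                for name in lms[side].points:
                    lms[side].points[name] = lms[side].points[name] + rng.uniform(-5, 5, 3)
            frame = build_frame(lms, COR, Side.RIGHT)
            for a in ("anterior", "superior", "lateral"):
                assert abs(np.linalg.norm(getattr(frame, a)) - 1.0) < 1e-9

    def test_missing_landmarks_rejected(self):
        lms = ideal_landmarks()
        del lms[Side.LEFT].points["ASIS"]
        with pytest.raises(SchemaError):
            build_frame(lms, COR, Side.RIGHT)


class TestViewPlanes:
    def _rim(self, cor=COR, radius=28.0, normal_axis=0):
        phi = np.radians(np.arange(0, 360, 30))
        u = np.eye(3)[(normal_axis + 1) % 3]
        v = np.eye(3)[(normal_axis + 2) % 3]
        return np.asarray(cor) + radius * (np.outer(np.cos(phi), u) + np.outer(np.sin(phi), v))

    def test_rim_in_yz_plane_gives_lateral_frontal_normal(self):
        frame = build_frame(ideal_landmarks(), COR, Side.RIGHT)
        planes = build_view_planes(frame, self._rim())
        n = planes["frontal"].plane.normal
        assert abs(abs(n[0]) - 1.0) < math.sin(math.radians(1.0))

    def test_mutual_orthogonality(self, cohort):
        for sp in cohort:
            side = sp.native_mesh.side
            frame = build_frame(sp.landmarks, COR * (1 if side is Side.RIGHT else -1), side)
            planes = build_view_planes(frame, sp.landmarks[side].rim_samples())
            normals = [planes[k].plane.normal for k in ("frontal", "sagittal", "axial")]
            for i in range(3):
                for j in range(i + 1, 3):
                    assert abs(normals[i] @ normals[j]) < math.sin(math.radians(1.0))

    def test_rigid_motion_equivariance(self):
        rng = np.random.default_rng(8)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = 0.7
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        rot = np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)
        motion = RigidTransform(matrix=rot, translation=rng.uniform(-30, 30, 3), kind="rotation")

        lms = ideal_landmarks()
        rim = self._rim()
        frame = build_frame(lms, COR, Side.RIGHT)
        planes = build_view_planes(frame, rim)

        moved_lms = {
            s: LandmarkSet(side=s, points={n: motion.apply(p) for n, p in ls.points.items()})
            for s, ls in lms.items()
        }
        frame_m = build_frame(moved_lms, motion.apply(COR), Side.RIGHT)
        planes_m = build_view_planes(frame_m, motion.apply(rim))
        for name in planes:
            for attr in ("u_axis", "v_axis", "normal"):
                got = getattr(planes_m[name].plane, attr)
                expected = motion.apply_vector(getattr(planes[name].plane, attr))
                assert np.allclose(got, expected, atol=1e-6)

    def test_too_few_rim_samples(self):
        frame = build_frame(ideal_landmarks(), COR, Side.RIGHT)
        with pytest.raises(Exception):
            build_view_planes(frame, self._rim()[:5])


class TestFrontalSectors:
    def _landmarks(self, view, angles):
        pts = {
            "ACETABULAR_NOTCH_ANTERIOR": landmark_at(view, COR, angles["an_a"]),
            "ISCHIATIC_NOTCH": landmark_at(view, COR, angles["in"]),
            "ASIS": landmark_at(view, COR, angles["asis"]),
            "ACETABULAR_NOTCH_POSTERIOR": landmark_at(view, COR, angles["an_p"]),
        }
        return LandmarkSet(side=Side.RIGHT, points=pts)

    def test_ninety_degree_spacing_sums_to_270(self):
        view = frontal_view()
        ls = self._landmarks(view, {"an_a": 270, "in": 180, "asis": 90, "an_p": 0})
        sectors = build_frontal_sectors(view, COR, ls)
        widths = {k: math.degrees(s.width) for k, s in sectors.items()}
        assert widths == pytest.approx({"PS-F": 90, "SS-F": 90, "AS-F": 90}, abs=1e-9)
        assert sum(widths.values()) == pytest.approx(270.0)

    def test_posterior_and_anterior_sectors_disjoint(self, cohort):
        for sp in cohort:
            side = sp.native_mesh.side
            _, sectors = build_all_sectors(
                build_frame(sp.landmarks, COR * (1 if side is Side.RIGHT else -1), side),
                sp.landmarks[side],
            )
            ps, as_ = sectors["PS-F"], sectors["AS-F"]
            mid_ps = ps.theta0 + ps.width / 2
            mid_as = as_.theta0 + as_.width / 2
            assert not as_.contains_angle(mid_ps)
            assert not ps.contains_angle(mid_as)

    def test_out_of_order_rays_rejected(self):
        view = frontal_view()
        # literal anatomical placement that breaks the published circular order
        ls = self._landmarks(view, {"an_a": 300, "in": 170, "asis": 60, "an_p": 250})
        with pytest.raises(DegenerateSectorError, match="circular order|wrap"):
            build_frontal_sectors(view, COR, ls)

    def test_nearly_coincident_rays_rejected(self):
        view = frontal_view()
        ls = self._landmarks(view, {"an_a": 270, "in": 90.5, "asis": 90, "an_p": 0})
        with pytest.raises(DegenerateSectorError, match="within 1°"):
            build_frontal_sectors(view, COR, ls)

    def test_landmark_on_cor_rejected(self):
        view = frontal_view()
        ls = self._landmarks(view, {"an_a": 270, "in": 180, "asis": 90, "an_p": 0})
        ls.points["ISCHIATIC_NOTCH"] = COR.copy()  # projects onto the CoR
        with pytest.raises(DegenerateSectorError, match="CoR"):
            build_frontal_sectors(view, COR, ls)


class TestSagittalSectors:
    def test_constructed_angles_give_110_and_70(self):
        plane = Plane3(origin=COR, u_axis=(1, 0, 0), v_axis=(0, 0, 1))  # u=lateral, v=superior
        view = ViewPlane("sagittal", plane)
        pts = {"ISCHIATIC_NOTCH": landmark_at(view, COR, 200.0)}
        phi = np.radians(np.arange(0, 360, 30))
        for i, p in enumerate(phi, start=1):  # rim circle in the y-z plane: superior point at 90 deg
            pts[f"RIM_SAMPLE_{i}"] = COR + 28.0 * np.array([0.0, math.cos(p), math.sin(p)])
        ls = LandmarkSet(side=Side.RIGHT, points=pts)
        sectors = build_sagittal_sectors(view, COR, ls)
        assert math.degrees(sectors["SS-S"].width) == pytest.approx(110.0, abs=1e-9)
        assert math.degrees(sectors["MS-S"].width) == pytest.approx(70.0, abs=1e-9)

    def test_union_spans_r1_to_caudal_extension(self, cohort):
        for sp in cohort:
            side = sp.native_mesh.side
            _, sectors = build_all_sectors(
                build_frame(sp.landmarks, COR * (1 if side is Side.RIGHT else -1), side),
                sp.landmarks[side],
            )
            ss, ms = sectors["SS-S"], sectors["MS-S"]
            assert ss.theta1 == pytest.approx(ms.theta0)  # shared boundary at r2-S
            total = math.degrees(ss.width + ms.width)
            assert total == pytest.approx(180.0, abs=1e-6)  # r1-S to its caudal extension

    def test_left_right_sector_layouts_congruent(self, intact_specimen):
        lay = {}
        for side in (Side.LEFT, Side.RIGHT):
            origin = COR * (1 if side is Side.RIGHT else -1)
            _, sectors = build_all_sectors(
                build_frame(intact_specimen.landmarks, origin, side),
                intact_specimen.landmarks[side],
            )
            lay[side] = {k: (s.theta0, s.width) for k, s in sectors.items()}
        for label in lay[Side.LEFT]:
            assert lay[Side.LEFT][label] == pytest.approx(lay[Side.RIGHT][label], abs=1e-9)


class TestAxialSectors:
    def test_line_and_sector_assignments(self, cohort):
        for sp in cohort:
            side = sp.native_mesh.side
            _, sectors = build_all_sectors(
                build_frame(sp.landmarks, COR * (1 if side is Side.RIGHT else -1), side),
                sp.landmarks[side],
            )
            assert {sectors["PS-A"].line_start.label, sectors["PS-A"].line_end.label} == {"r1-A", "r2-A"}
            assert {sectors["MS-A"].line_start.label, sectors["MS-A"].line_end.label} == {"r2-A", "r3-A"}
            assert {sectors["AS-A"].line_start.label, sectors["AS-A"].line_end.label} == {"r3-A", "r4-A"}
            # contiguity: MS-A shares one boundary with each neighbour
            assert sectors["PS-A"].theta0 == pytest.approx(sectors["MS-A"].theta1)
            assert sectors["MS-A"].theta0 == pytest.approx(sectors["AS-A"].theta1)

    def test_rigid_motion_equivariance_of_intervals(self, intact_specimen):
        rng = np.random.default_rng(13)
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        rot = np.eye(3) + math.sin(0.5) * k + (1 - math.cos(0.5)) * (k @ k)
        motion = RigidTransform(matrix=rot, translation=rng.uniform(-40, 40, 3), kind="rotation")

        side = intact_specimen.native_mesh.side
        origin = COR * (1 if side is Side.RIGHT else -1)
        lms = intact_specimen.landmarks
        _, sectors = build_all_sectors(build_frame(lms, origin, side), lms[side])
        moved = {
            s: LandmarkSet(side=s, points={n: motion.apply(p) for n, p in ls.points.items()})
            for s, ls in lms.items()
        }
        _, sectors_m = build_all_sectors(build_frame(moved, motion.apply(origin), side), moved[side])
        for label in sectors:
            assert sectors_m[label].width == pytest.approx(sectors[label].width, abs=1e-6)
            assert sectors_m[label].theta0 == pytest.approx(sectors[label].theta0, abs=1e-6)


def make_sector(theta0_deg, theta1_deg, view=None):
    view = view or frontal_view()
    t0, t1 = math.radians(theta0_deg), math.radians(theta1_deg)
    origin2 = view.plane.to_plane_coords(COR)
    return Sector(
        label="PS-F", view=view,
        line_start=ReferenceLine("r1-F", t0, origin2),
        line_end=ReferenceLine("r2-F", t1, origin2),
        theta0=t0 % (2 * math.pi), theta1=t1 % (2 * math.pi),
    )


def circle_profile(radius):
    return lambda theta: np.full(np.shape(theta), float(radius))


class TestSectorPolygons:
    def test_quarter_circle_closed_form(self):
        sector = make_sector(0, 90)
        poly = native_sector_polygon(sector, circle_profile(10.0), step_deg=1.0)
        assert poly.area == pytest.approx(math.pi * 100.0 / 4.0, rel=1e-3)

    @pytest.mark.parametrize("width_deg", [30.0, 90.0, 160.0])
    def test_circular_sector_converges_with_fan_step(self, width_deg):
        sector = make_sector(10, 10 + width_deg)
        exact = 0.5 * 15.0**2 * math.radians(width_deg)
        coarse = abs(native_sector_polygon(sector, circle_profile(15.0), step_deg=2.0).area - exact)
        fine = abs(native_sector_polygon(sector, circle_profile(15.0), step_deg=0.25).area - exact)
        assert fine < coarse
        assert coarse / exact < 1e-3

    def test_star_shaped_rim_matches_quadrature_oracle(self):
        def rho(theta):
            return 10.0 + 2.0 * np.sin(3.0 * np.asarray(theta))

        sector = make_sector(20, 155)
        theta_pts = np.radians(np.arange(0, 360, 0.5))
        rim_pts = np.column_stack([rho(theta_pts) * np.cos(theta_pts), rho(theta_pts) * np.sin(theta_pts)])
        profile = RimProfile(rim_pts + COR[[1, 2]] * 0, origin=(0.0, 0.0))
        poly = native_sector_polygon(sector, profile, step_deg=1.0)
        oracle = quadrature_sector_area(rho, math.radians(20), math.radians(155), step_deg=0.01)
        assert poly.area == pytest.approx(oracle, rel=5e-3)

    def test_incomplete_rim_raises(self):
        def gappy(theta):
            t = np.asarray(theta, dtype=float)
            out = np.full(t.shape, 10.0)
            out[np.degrees(t % (2 * math.pi)) > 45] = np.nan
            return out

        with pytest.raises(IncompleteRimError):
            native_sector_polygon(make_sector(0, 90), gappy)

    def test_intact_side_reproduces_native_polygon(self):
        sector = make_sector(0, 90)
        native = native_sector_polygon(sector, circle_profile(10.0))
        defect = defect_sector_polygon(sector, circle_profile(10.0), np.empty((0, 2)))
        assert defect.area == pytest.approx(native.area, rel=1e-12)
        assert not defect.unmeasurable

    def test_radial_enlargement_scales_area_by_factor_squared(self):
        sector = make_sector(0, 90)
        native = native_sector_polygon(sector, circle_profile(10.0))
        theta = np.radians(np.arange(-0.5, 90.6, 0.25))
        border = 15.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        defect = defect_sector_polygon(sector, circle_profile(10.0), border)
        assert defect.area / native.area == pytest.approx(2.25, rel=2e-3)

    def test_polygon_endpoints_lie_on_bounding_lines(self):
        sector = make_sector(30, 140)
        theta = np.radians(np.arange(29.5, 140.6, 0.2))
        border = 13.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        poly = defect_sector_polygon(sector, circle_profile(9.0), border)
        for vertex, line in ((poly.vertices[1], sector.line_start), (poly.vertices[-1], sector.line_end)):
            rel = vertex - line.origin
            cross = rel[0] * math.sin(line.angle) - rel[1] * math.cos(line.angle)
            assert abs(cross) < 1e-6
            assert rel @ line.direction() > 0

    def test_unmeasurable_flag_when_bone_absent(self):
        sector = make_sector(0, 90)
        # pathological geometry present along <50% of rays
        theta = np.radians(np.arange(0, 30, 0.5))
        presence = 9.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        poly = defect_sector_polygon(
            sector, circle_profile(10.0), np.empty((0, 2)), presence_points2d=presence
        )
        assert poly.unmeasurable

    def test_area_scales_quadratically_with_specimen_size(self):
        sector = make_sector(15, 105)
        small = native_sector_polygon(sector, circle_profile(10.0)).area
        large = native_sector_polygon(sector, circle_profile(30.0)).area
        assert large / small == pytest.approx(9.0, rel=1e-9)


class TestFirstHitProfile:
    def test_nearest_crossing_wins(self):
        inner = [np.array([[2.0, -1.0], [2.0, 1.0]])]
        outer = [np.array([[5.0, -1.0], [5.0, 1.0]])]
        from acetair.geometry import PlanarContour

        contours = [PlanarContour(points=c, closed=False) for c in (outer[0], inner[0])]
        prof = FirstHitProfile(contours)
        assert prof(0.0) == pytest.approx(2.0)

    def test_miss_gives_nan(self):
        from acetair.geometry import PlanarContour

        prof = FirstHitProfile([PlanarContour(points=np.array([[2.0, -1.0], [2.0, 1.0]]), closed=False)])
        assert math.isnan(prof(math.pi))
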