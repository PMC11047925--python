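"""Geometric primitives for acetabular surface analysis.

Pure geometry, no anatomy: least-squares sphere and plane fitting,
landmark-based reflection (mirroring), orthogonal projection onto a plane,
mesh–plane cross-sections, radial extent queries and planar polygon areas.
All coordinates are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "GeometryError",
    "DegenerateInputError",
    "InvalidPolygonError",
    "Sphere",
    "Plane3",
    "RigidTransform",
    "PlanarContour",
    "fit_sphere",
    "fit_plane",
    "mirror_transform",
    "project_to_plane",
    "cross_section",
    "max_radial_extent",
    "polygon_area",
]

_UNIT_TOL = 1e-9


class GeometryError(ValueError):
    """Base class for geometric failures."""


class DegenerateInputError(GeometryError):
    """Input configuration is rank-deficient (collinear/coplanar/too few points)."""


class InvalidPolygonError(GeometryError):
    """Polygon is not simple (self-intersecting) or has fewer than 3 vertices."""


def _as_points(points, min_count: int, name: str) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"{name}: expected an (N, 3) array, got shape {pts.shape}")
    if pts.shape[0] < min_count:
        raise DegenerateInputError(f"{name}: need at least {min_count} points, got {pts.shape[0]}")
    return pts


@dataclass(frozen=True)
class Sphere:
    """A sphere fitted to surface samples; ``center`` is used as the hip centre of rotation."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if not self.radius > 0:
            raise GeometryError(f"sphere radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class Plane3:
    """An oriented plane with an in-plane orthonormal basis.

    ``u_axis``/``v_axis`` span the plane; ``normal = u × v``. Points are mapped
    between world space and in-plane (u, v) coordinates with
    :meth:`to_plane_coords` / :meth:`to_world`.
    """

    origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    normal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        origin = np.asarray(self.origin, dtype=float).reshape(3)
        u = np.asarray(self.u_axis, dtype=float).reshape(3)
        v = np.asarray(self.v_axis, dtype=float).reshape(3)
        n = np.cross(u, v) if self.normal is None else np.asarray(self.normal, dtype=float).reshape(3)
        for vec, label in ((u, "u_axis"), (v, "v_axis"), (n, "normal")):
            if abs(np.linalg.norm(vec) - 1.0) > 1e-6:
                raise GeometryError(f"{label} must be a unit vector")
        if abs(np.dot(u, v)) > 1e-6:
            raise GeometryError("u_axis and v_axis must be orthogonal")
        if np.linalg.norm(np.cross(u, v) - n) > 1e-6:
            raise GeometryError("normal must equal u × v")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "u_axis", u)
        object.__setattr__(self, "v_axis", v)
        object.__setattr__(self, "normal", n)

    def to_plane_coords(self, points) -> np.ndarray:
        """Orthogonally project world points into (u, v) coordinates. Accepts (3,) or (N, 3)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        rel = np.atleast_2d(pts) - self.origin
        uv = np.column_stack([rel @ self.u_axis, rel @ self.v_axis])
        return uv[0] if single else uv

    def to_world(self, uv) -> np.ndarray:
        """Lift (u, v) coordinates back to 3D points on the plane."""
        arr = np.asarray(uv, dtype=float)
        single = arr.ndim == 1
        arr2 = np.atleast_2d(arr)
        world = self.origin + np.outer(arr2[:, 0], self.u_axis) + np.outer(arr2[:, 1], self.v_axis)
        return world[0] if single else world

    def signed_distance(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        d = (np.atleast_2d(pts) - self.origin) @ self.normal
        return float(d[0]) if single else d


@dataclass(frozen=True)
class RigidTransform:
    """Orthogonal 3×3 matrix plus translation; ``kind`` is 'reflection' or 'rotation'."""

    matrix: np.ndarray
    translation: np.ndarray
    kind: str

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if np.linalg.norm(m @ m.T - np.eye(3)) > 1e-9:
            raise GeometryError("transform matrix must be orthogonal")
        det = np.linalg.det(m)
        expected = -1.0 if self.kind == "reflection" else 1.0
        if self.kind not in ("reflection", "rotation"):
            raise GeometryError(f"unknown transform kind {self.kind!r}")
        if abs(det - expected) > 1e-9:
            raise GeometryError(f"{self.kind} must have determinant {expected:+.0f}, got {det:.6f}")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        out = np.atleast_2d(pts) @ self.matrix.T + self.translation
        return out[0] if single else out

    def apply_vector(self, vectors) -> np.ndarray:
        """Transform direction vectors (no translation)."""
        vec = np.asarray(vectors, dtype=float)
        single = vec.ndim == 1
        out = np.atleast_2d(vec) @ self.matrix.T
        return out[0] if single else out

    @staticmethod
    def reflection_across(normal, point) -> "RigidTransform":
        """Reflection across the plane through ``point`` with unit ``normal``."""
        n = np.asarray(normal, dtype=float).reshape(3)
        n = n / np.linalg.norm(n)
        p = np.asarray(point, dtype=float).reshape(3)
        m = np.eye(3) - 2.0 * np.outer(n, n)
        t = 2.0 * np.dot(p, n) * n
        return RigidTransform(matrix=m, translation=t, kind="reflection")


@dataclass(frozen=True)
class PlanarContour:
    """A mesh–plane intersection polyline in a plane's (u, v) coordinates."""

    points: np.ndarray  # (N, 2)
    closed: bool


def fit_sphere(points) -> Sphere:
    """Least-squares sphere through 3D samples (Coope/Kåsa linearization).

    Solves ``|p|² = 2 c·p + k`` for centre ``c`` and ``k = r² − |c|²``. Exact
    on noiseless spherical samples; raises :class:`DegenerateInputError` for
    fewer than 4 points or coplanar/collinear configurations (rank-deficient
    design matrix).
    """
    pts = _as_points(points, 4, "fit_sphere")
    a = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = np.einsum("ij,ij->i", pts, pts)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise DegenerateInputError("fit_sphere: points are coplanar or otherwise degenerate")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateInputError("fit_sphere: negative squared radius (degenerate input)")
    return Sphere(center=center, radius=float(np.sqrt(r2)))


# Axis completion for fitted planes: prefer the global superior (z) axis,
# falling back to the anterior (y) axis when the normal is (near-)parallel to z.
_SUPERIOR = np.array([0.0, 0.0, 1.0])
_ANTERIOR = np.array([0.0, 1.0, 0.0])


def complete_plane_axes(normal: np.ndarray, superior=None, anterior=None) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane (u, v) basis for a given unit normal.

    u is the normalized in-plane projection of the superior reference axis
    (or of the anterior axis if superior is within ~1e-6 of the normal);
    v = normal × u, so that u × v = normal.
    """
    n = np.asarray(normal, dtype=float).reshape(3)
    sup = _SUPERIOR if superior is None else np.asarray(superior, dtype=float)
    ant = _ANTERIOR if anterior is None else np.asarray(anterior, dtype=float)
    u = sup - np.dot(sup, n) * n
    if np.linalg.norm(u) < 1e-6:
        u = ant - np.dot(ant, n) * n
    u = u / np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def fit_plane(points, superior=None, anterior=None) -> Plane3:
    """Total-least-squares plane through the centroid of 3D samples.

    The normal is the smallest principal axis; the in-plane axes follow
    :func:`complete_plane_axes`. Collinear input raises
    :class:`DegenerateInputError`.
    """
    pts = _as_points(points, 3, "fit_plane")
    centroid = pts.mean(axis=0)
    _, svals, vt = np.linalg.svd(pts - centroid)
    scale = max(svals[0], 1.0)
    if len(svals) < 2 or svals[1] / scale < 1e-12:
        raise DegenerateInputError("fit_plane: points are collinear")
    normal = vt[2]
    u, v = complete_plane_axes(normal, superior=superior, anterior=anterior)
    return Plane3(origin=centroid, u_axis=u, v_axis=v, normal=np.cross(u, v))


def mirror_transform(pairs) -> RigidTransform:
    """Reflection across the mid-sagittal plane estimated from bilateral landmark pairs.

    ``pairs`` is a sequence of (left_point, right_point). The mirror plane
    passes through the centroid of the pair midpoints. Its normal is the mean
    of the right−left difference vectors; when three or more well-spread
    midpoints are available the normal is refined to the smallest principal
    axis of the midpoints (sign-aligned with the initial estimate), since the
    midpoints of truly symmetric landmarks lie on the mirror plane.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 3 or arr.shape[1:] != (2, 3):
        arr = np.stack([np.stack([np.asarray(l, float), np.asarray(r, float)]) for l, r in pairs])
    if arr.shape[0] < 2:
        raise DegenerateInputError("mirror_transform: need at least 2 landmark pairs (ASIS and pubic tubercle)")
    left, right = arr[:, 0, :], arr[:, 1, :]
    diffs = right - left
    n0 = diffs.mean(axis=0)
    norm0 = np.linalg.norm(n0)
    if norm0 < 1e-12:
        raise DegenerateInputError("mirror_transform: landmark pairs coincide; mirror direction undefined")
    n0 = n0 / norm0
    midpoints = 0.5 * (left + right)
    centroid = midpoints.mean(axis=0)
    normal = n0
    if len(midpoints) >= 3:
        _, svals, vt = np.linalg.svd(midpoints - centroid)
        # Refine only when midpoints span a 2D patch of the mirror plane.
        if svals[1] > 1e-9 * max(svals[0], 1.0):
            cand = vt[2]
            if abs(np.dot(cand, n0)) > 0.5:
                normal = cand if np.dot(cand, n0) > 0 else -cand
    return RigidTransform.reflection_across(normal, centroid)


def project_to_plane(point, plane: Plane3) -> np.ndarray:
    """Orthogonal projection into the plane's (u, v) coordinates (mm)."""
    return plane.to_plane_coords(point)


def cross_section(mesh, plane: Plane3) -> list[PlanarContour]:
    """Intersect a triangle mesh with a plane.

    Returns the intersection contours as ordered polylines in the plane's
    (u, v) coordinates (closed loops flagged). Vertices lying exactly on the
    plane have their signed distance nudged by +1e-9 mm so every crossing face
    contributes exactly one segment. An empty list is a valid result.
    """
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if len(vertices) == 0 or len(faces) == 0:
        return []
    d = plane.signed_distance(vertices)
    d = np.where(d == 0.0, 1e-9, d)
    fd = d[faces]  # (F, 3)
    pos = fd > 0
    npos = pos.sum(axis=1)
    crossing = (npos == 1) | (npos == 2)
    if not crossing.any():
        return []

    # Each crossing face yields one segment whose endpoints lie on two of its
    # edges. Identify edges by sorted vertex index pairs so shared edges chain
    # contiguous faces into polylines.
    seg_edges = []   # (segment, 2) edge keys
    seg_points = []  # (segment, 2, 3) endpoints
    edge_point: dict[tuple[int, int], np.ndarray] = {}
    for fidx in np.nonzero(crossing)[0]:
        tri = faces[fidx]
        dd = fd[fidx]
        odd = int(np.nonzero(pos[fidx] if npos[fidx] == 1 else ~pos[fidx])[0][0])
        others = [(odd + 1) % 3, (odd + 2) % 3]
        keys = []
        for o in others:
            i, j = int(tri[odd]), int(tri[o])
            t = dd[odd] / (dd[odd] - dd[o])
            pt = vertices[i] + t * (vertices[j] - vertices[i])
            key = (i, j) if i < j else (j, i)
            edge_point.setdefault(key, pt)
            keys.append(key)
        seg_edges.append(tuple(keys))
        seg_points.append(None)

    # Chain segments through shared edge keys.
    adjacency: dict[tuple[int, int], list[int]] = {}
    for sidx, (k0, k1) in enumerate(seg_edges):
        adjacency.setdefault(k0, []).append(sidx)
        adjacency.setdefault(k1, []).append(sidx)

    unused = set(range(len(seg_edges)))
    contours: list[PlanarContour] = []
    while unused:
        start = unused.pop()
        k0, k1 = seg_edges[start]
        chain = [k0, k1]
        # extend forward from k1, then backward from k0
        for end_idx, reverse in ((1, False), (0, True)):
            current_key = chain[-1] if not reverse else chain[0]
            prev_seg = start
            while True:
                nxt = [s for s in adjacency.get(current_key, []) if s in unused]
                if not nxt:
                    break
                seg = nxt[0]
                unused.discard(seg)
                a, b = seg_edges[seg]
                current_key = b if a == current_key else a
                if reverse:
                    chain.insert(0, current_key)
                else:
                    chain.append(current_key)
                prev_seg = seg
            if reverse:
                break
            # switch to backward extension
            if chain[0] == chain[-1]:
                break  # already a closed loop
        closed = len(chain) > 2 and chain[0] == chain[-1]
        keys = chain[:-1] if closed else chain
        pts3d = np.array([edge_point[k] for k in keys])
        contours.append(PlanarContour(points=plane.to_plane_coords(pts3d), closed=closed))
    return contours


def max_radial_extent(points, origin, angle: float, half_width: float):
    """Largest distance from ``origin`` to any 2D point whose polar angle lies
    within ``±half_width`` of ``angle`` (radians). Returns None when no point
    falls inside the angular window."""
    if half_width < 0:
        raise GeometryError("max_radial_extent: half_width must be non-negative")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return None
    rel = pts - np.asarray(origin, dtype=float).reshape(2)
    radii = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    delta = np.abs((theta - angle + np.pi) % (2.0 * np.pi) - np.pi)
    mask = (delta <= half_width) & (radii > 0)
    if not mask.any():
        return None
    return float(radii[mask].max())


def polygon_area(vertices) -> float:
    """Absolute shoelace area of a simple planar polygon (mm²).

    Orientation-independent. Raises :class:`InvalidPolygonError` for
    self-intersecting polygons or fewer than 3 vertices.
    """
    pts = np.atleast_2d(np.asarray(vertices, dtype=float))
    if pts.shape[0] >= 2 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if pts.shape[0] < 3:
        raise InvalidPolygonError("polygon needs at least 3 distinct vertices")
    poly = _ShapelyPolygon(pts)
    if not poly.is_simple or not poly.is_valid:
        raise InvalidPolygonError("polygon is self-intersecting")
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area)
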