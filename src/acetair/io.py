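"""File formats: STL meshes, landmark JSON, reports, and the published six-specimen table.

STL is parsed directly (both ASCII and binary flavours) because the format is
trivial: no external mesh library is required. Landmarks travel in a single
JSON document covering both sides, since mirroring needs bilateral pairs.
"""

from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Side",
    "Role",
    "LandmarkName",
    "FormatError",
    "SchemaError",
    "SurfaceMesh",
    "LandmarkSet",
    "SpecimenRecord",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "load_table3_fixture",
    "report_to_frame",
    "write_report_csv",
    "write_report_json",
    "read_report_csv",
    "SECTOR_LABELS",
    "PLANE_OF_SECTOR",
]

SECTOR_LABELS = ("PS-F", "SS-F", "AS-F", "SS-S", "MS-S", "PS-A", "MS-A", "AS-A")
PLANE_OF_SECTOR = {
    "PS-F": "frontal", "SS-F": "frontal", "AS-F": "frontal",
    "SS-S": "sagittal", "MS-S": "sagittal",
    "PS-A": "axial", "MS-A": "axial", "AS-A": "axial",
}


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    @property
    def opposite(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class Role(str, Enum):
    NATIVE = "native"
    PATHOLOGICAL = "pathological"


class LandmarkName(str, Enum):
    """Named anatomical points used for mirroring, frames and sector lines."""

    ASIS = "ASIS"
    PUBIC_TUBERCLE = "PUBIC_TUBERCLE"
    ISCHIATIC_NOTCH = "ISCHIATIC_NOTCH"
    ACETABULAR_NOTCH_ANTERIOR = "ACETABULAR_NOTCH_ANTERIOR"
    ACETABULAR_NOTCH_POSTERIOR = "ACETABULAR_NOTCH_POSTERIOR"
    ISCHIATIC_SPINE = "ISCHIATIC_SPINE"
    SUPERIOR_PUBIC_RAMUS = "SUPERIOR_PUBIC_RAMUS"


RIM_PREFIX = "RIM_SAMPLE_"


def _is_valid_name(name: str) -> bool:
    if name in LandmarkName._value2member_map_:
        return True
    if name.startswith(RIM_PREFIX):
        suffix = name[len(RIM_PREFIX):]
        return suffix.isdigit()
    return False


class FormatError(ValueError):
    """Unreadable or structurally invalid file."""


class SchemaError(FormatError):
    """JSON document does not match the landmark schema."""


@dataclass
class SurfaceMesh:
    """Triangle surface mesh in millimetres.

    Degenerate (zero-area) faces are dropped on construction and the count is
    logged; face indices are validated against the vertex array.
    """

    vertices: np.ndarray  # (V, 3) float
    faces: np.ndarray     # (F, 3) int
    side: Side = Side.RIGHT
    role: Role = Role.NATIVE

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.side = Side(self.side)
        self.role = Role(self.role)
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise FormatError("empty mesh: no vertices or no faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise FormatError("face indices out of range")
        areas = self._face_areas()
        degenerate = areas < 1e-12
        if degenerate.any():
            logger.warning("dropping %d degenerate (zero-area) faces", int(degenerate.sum()))
            self.faces = self.faces[~degenerate]
            if len(self.faces) == 0:
                raise FormatError("mesh contains only degenerate faces")

    def _face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def transformed(self, transform) -> "SurfaceMesh":
        """Return a copy with vertices mapped through a RigidTransform.

        Reflections invert triangle orientation, which is irrelevant here:
        sections and projections are orientation-agnostic.
        """
        return SurfaceMesh(
            vertices=transform.apply(self.vertices),
            faces=self.faces.copy(),
            side=self.side.opposite if transform.kind == "reflection" else self.side,
            role=self.role,
        )


@dataclass
class LandmarkSet:
    """Named anatomical points (mm) of one hemipelvis side."""

    side: Side
    points: dict = field(default_factory=dict)

    def __post_init__(self):
        self.side = Side(self.side)
        clean = {}
        for name, xyz in self.points.items():
            if not _is_valid_name(name):
                raise SchemaError(
                    f"unknown landmark name {name!r}; allowed: "
                    f"{[m.value for m in LandmarkName]} or {RIM_PREFIX}<i>"
                )
            clean[name] = np.asarray(xyz, dtype=float).reshape(3)
        self.points = clean

    def __contains__(self, name) -> bool:
        return str(getattr(name, "value", name)) in self.points

    def get(self, name) -> np.ndarray:
        key = str(getattr(name, "value", name))
        if key not in self.points:
            raise KeyError(f"landmark {key!r} missing on side {self.side.value}")
        return self.points[key]

    def rim_samples(self) -> np.ndarray:
        """Acetabular rim sample points, ordered by index, shape (N, 3)."""
        items = sorted(
            ((int(k[len(RIM_PREFIX):]), v) for k, v in self.points.items() if k.startswith(RIM_PREFIX)),
            key=lambda kv: kv[0],
        )
        if not items:
            return np.empty((0, 3))
        return np.stack([v for _, v in items])

    @property
    def n_rim_samples(self) -> int:
        return sum(1 for k in self.points if k.startswith(RIM_PREFIX))

    def require(self, *names) -> None:
        missing = [str(getattr(n, "value", n)) for n in names if n not in self]
        if missing:
            raise SchemaError(f"side {self.side.value}: missing required landmarks {missing}")


@dataclass
class SpecimenRecord:
    """Demographic / clinical metadata carried through to reports."""

    specimen_id: str = ""
    age: int | None = None
    sex: str | None = None
    side: Side | None = None
    diagnosis: str | None = None
    paprosky_type: str | None = None  # free-text metadata; never classified here
    rim_diameter_mm: float | None = None

    def __post_init__(self):
        if self.side is not None:
            self.side = Side(self.side)
        if self.rim_diameter_mm is not None and not self.rim_diameter_mm > 0:
            raise ValueError("rim diameter must be positive when provided")


# ---------------------------------------------------------------------------
# STL

def read_mesh(path, role=Role.NATIVE, side=Side.RIGHT) -> SurfaceMesh:
    """Read a binary or ASCII STL file into a :class:`SurfaceMesh`.

    Duplicate per-facet vertices are merged exactly (STL stores each triangle
    independently). Units are taken to be millimetres; no autodetection.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = path.read_bytes()
    if len(raw) < 15:
        raise FormatError(f"{path}: too short to be an STL file")
    triangles = None
    if raw[:5].lower() == b"solid":
        try:
            triangles = _parse_ascii_stl(raw.decode("ascii", errors="strict"))
        except (UnicodeDecodeError, FormatError):
            triangles = None  # binary files sometimes start with 'solid'
    if triangles is None:
        triangles = _parse_binary_stl(raw, path)
    if len(triangles) == 0:
        raise FormatError(f"{path}: STL file contains no facets")
    flat = triangles.reshape(-1, 3)
    vertices, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    mesh = SurfaceMesh(vertices=vertices, faces=faces, side=side, role=role)
    logger.info("read %s: %d vertices, %d faces", path.name, mesh.n_vertices, mesh.n_faces)
    return mesh


def _parse_ascii_stl(text: str) -> np.ndarray:
    coords = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("vertex"):
            parts = line.split()
            if len(parts) != 4:
                raise FormatError("malformed ASCII STL vertex line")
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if len(coords) % 3 != 0:
        raise FormatError("ASCII STL vertex count not a multiple of 3")
    return np.asarray(coords, dtype=np.float64).reshape(-1, 3, 3)


def _parse_binary_stl(raw: bytes, path) -> np.ndarray:
    if len(raw) < 84:
        raise FormatError(f"{path}: binary STL shorter than its 84-byte header")
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + count * 50
    if len(raw) < expected:
        raise FormatError(f"{path}: binary STL truncated ({len(raw)} < {expected} bytes)")
    data = np.frombuffer(raw, dtype=np.uint8, count=count * 50, offset=84)
    floats = data.reshape(count, 50)[:, :48].copy().view("<f4").reshape(count, 4, 3)
    return floats[:, 1:4, :].astype(np.float64)


def write_mesh(path, mesh: SurfaceMesh, ascii_format: bool = False) -> None:
    """Write a mesh as STL (binary by default)."""
    path = Path(path)
    tri = mesh.vertices[mesh.faces]
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1)
    normals = normals / np.where(norms > 0, norms, 1.0)[:, None]
    if ascii_format:
        lines = ["solid acetair"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append("endsolid acetair")
        path.write_text("\n".join(lines) + "\n")
        return
    count = len(tri)
    buf = bytearray(struct.pack("<80sI", b"acetair binary STL", count))
    rec = np.zeros((count, 50), dtype=np.uint8)
    packed = np.concatenate([normals.astype("<f4"), tri.reshape(count, 9).astype("<f4")], axis=1)
    rec[:, :48] = packed.view(np.uint8).reshape(count, 48)
    buf.extend(rec.tobytes())
    path.write_bytes(bytes(buf))


# ---------------------------------------------------------------------------
# Landmark JSON

def read_landmarks(path) -> dict:
    """Read a landmark JSON file; returns ``{Side: LandmarkSet}`` for the sides present.

    Schema::

        {"specimen": str,
         "landmarks": [{"name": str, "side": "left"|"right", "xyz": [x, y, z]}, ...]}
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "landmarks" not in doc:
        raise SchemaError(f"{path}: missing required top-level field 'landmarks'")
    per_side: dict[Side, dict] = {}
    for i, entry in enumerate(doc["landmarks"]):
        for fieldname in ("name", "side", "xyz"):
            if fieldname not in entry:
                raise SchemaError(f"{path}: landmark #{i} missing required field {fieldname!r}")
        try:
            side = Side(entry["side"])
        except ValueError as exc:
            raise SchemaError(f"{path}: landmark #{i} has invalid side {entry['side']!r}") from exc
        xyz = entry["xyz"]
        if not (isinstance(xyz, (list, tuple)) and len(xyz) == 3):
            raise SchemaError(f"{path}: landmark #{i} xyz must be a 3-element list")
        per_side.setdefault(side, {})[entry["name"]] = xyz
    return {side: LandmarkSet(side=side, points=pts) for side, pts in per_side.items()}


def write_landmarks(path, landmark_sets, specimen: str = "") -> None:
    """Write landmark sets (mapping or iterable of LandmarkSet) as landmark JSON."""
    sets = landmark_sets.values() if isinstance(landmark_sets, dict) else landmark_sets
    entries = []
    for ls in sets:
        for name, xyz in sorted(ls.points.items()):
            entries.append({"name": name, "side": ls.side.value, "xyz": [float(c) for c in xyz]})
    Path(path).write_text(json.dumps({"specimen": specimen, "landmarks": entries}, indent=1))


# ---------------------------------------------------------------------------
# Published six-specimen results (defected sector areas and AIR percentages)

def load_table3_fixture() -> pd.DataFrame:
    """Load the packaged six-specimen reference table.

    One row per (specimen, sector): columns ``specimen``, ``diameter_mm``,
    ``plane``, ``sector``, ``area_mm2`` (defected sector area) and
    ``air_percent``. 6 specimens × 8 sectors = 48 rows.
    """
    with resources.files("acetair.data").joinpath("table3.csv").open("r") as fh:
        df = pd.read_csv(fh)
    df["plane"] = df["sector"].map(PLANE_OF_SECTOR)
    return df


# ---------------------------------------------------------------------------
# Reports

def report_to_frame(report) -> pd.DataFrame:
    """Flatten a SpecimenReport into the canonical one-row-per-sector table."""
    rows = []
    for res in report.results:
        rows.append(
            {
                "specimen": report.record.specimen_id,
                "plane": PLANE_OF_SECTOR[res.sector],
                "sector": res.sector,
                "area_native_mm2": res.a_nat,
                "area_defect_mm2": res.a_def,
                "air_percent": res.air,
                "grade": res.grade,
                "unmeasurable": res.unmeasurable,
            }
        )
    return pd.DataFrame(rows)


def write_report_csv(path, report) -> None:
    report_to_frame(report).to_csv(path, index=False, float_format="%.6g")


def write_report_json(path, report) -> None:
    doc = {
        "specimen": report.record.specimen_id,
        "side": report.record.side.value if report.record.side else None,
        "paprosky_type": report.record.paprosky_type,
        "rim_diameter_mm": report.rim_diameter_mm,
        "sectors": [
            {
                "sector": res.sector,
                "plane": PLANE_OF_SECTOR[res.sector],
                "area_native_mm2": res.a_nat,
                "area_defect_mm2": res.a_def,
                "air_percent": res.air,
                "grade": res.grade,
                "unmeasurable": res.unmeasurable,
            }
            for res in report.results
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_report_csv(path) -> pd.DataFrame:
    """Read a per-specimen report CSV back into the canonical table."""
    df = pd.read_csv(path)
    required = {"specimen", "sector", "air_percent"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: report is missing columns {sorted(required - set(df.columns))}")
    return df
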