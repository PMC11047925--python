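import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acetair import analysis, synthetic
from acetair.io import SurfaceMesh, Side, Role

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def uv_sphere_mesh(radius=1.0, center=(0.0, 0.0, 0.0), step_deg=5.0) -> SurfaceMesh:
    """Closed lat-long sphere mesh used by cross-section tests."""
    center = np.asarray(center, dtype=float)
    n_lat = max(4, int(round(180.0 / step_deg)))
    n_lon = max(8, int(round(360.0 / step_deg)))
    lats = np.linspace(0.0, math.pi, n_lat + 1)[1:-1]
    lons = np.arange(n_lon) * (2.0 * math.pi / n_lon)
    ring = np.stack(
        [
            np.outer(np.sin(lats), np.cos(lons)),
            np.outer(np.sin(lats), np.sin(lons)),
            np.outer(np.cos(lats), np.ones(n_lon)),
        ],
        axis=-1,
    ).reshape(-1, 3)
    north, south = np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])
    vertices = center + radius * np.vstack([north, ring, south])
    faces = []
    for j in range(n_lon):
        faces.append([0, 1 + j, 1 + (j + 1) % n_lon])
    for i in range(len(lats) - 1):
        r0, r1 = 1 + i * n_lon, 1 + (i + 1) * n_lon
        for j in range(n_lon):
            jn = (j + 1) % n_lon
            faces.append([r0 + j, r1 + j, r1 + jn])
            faces.append([r0 + j, r1 + jn, r0 + jn])
    last = 1 + (len(lats) - 1) * n_lon
    tail = len(vertices) - 1
    for j in range(n_lon):
        faces.append([tail, last + (j + 1) % n_lon, last + j])
    return SurfaceMesh(vertices=vertices, faces=np.asarray(faces), side=Side.RIGHT, role=Role.NATIVE)


@pytest.fixture(scope="session")
def cohort():
    """The default six-specimen synthetic cohort (noiseless, deterministic)."""
    return synthetic.make_cohort(6, seed=1)


@pytest.fixture(scope="session")
def cohort_reports(cohort):
    """Pipeline reports for the six-specimen cohort."""
    return [
        analysis.analyze_specimen(sp.native_mesh, sp.pathological_mesh, sp.landmarks, record=sp.record)
        for sp in cohort
    ]


@pytest.fixture(scope="session")
def intact_specimen():
    """A defect-free paired specimen (left hemipelvis pathological side)."""
    return synthetic.make_specimen(
        synthetic.SyntheticSpec(side=Side.LEFT, specimen_id="intact")
    )


@pytest.fixture(scope="session")
def single_defect_specimen():
    """One medially located defect of moderate extent with clean ground truth."""
    spec = synthetic.SyntheticSpec(
        defects=(synthetic.DefectSpec("MS-S", factor=math.sqrt(2.0), coverage=0.5),),
        specimen_id="single",
    )
    return synthetic.make_specimen(spec)
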