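# Methods

This note documents the model implemented by `acetair`, the parameters that
matter, what the synthetic-specimen generator does and does not emulate, and
the numerical choices made where the procedure left room.

## The measurement model

A unilateral acetabular defect is quantified against the patient's own healthy
contralateral anatomy. Three stages:

**1. Mirroring.** Bilateral anterior superior iliac spines (ASIS) and pubic
tubercles define an estimated mid-sagittal plane: its normal is the mean of
the right−left landmark difference vectors, refined to the smallest principal
axis of the pair midpoints when three or more well-spread midpoints are
available, and the plane passes through the midpoint centroid. The pathological
hemipelvis is reflected across this plane onto the native side, so all
measurements take place in native coordinates with the native CoR, rim and
reference lines overlaid on the pathological bone. The reflection is a single
landmark-guided operation; no ICP or other global refinement is applied,
because the reference procedure is a one-shot mirroring-tool call and any
refinement would re-fit the pathological geometry that we are trying to
measure against.

**2. Planes and sectors.** The hip centre of rotation (CoR) is the centre of a
least-squares sphere on the native acetabular surface. Surface points are
selected automatically: mesh vertices within 0.35–1.3 rim radii of the
rim-circle centre on the medial side of the rim plane, followed by one
trim-and-refit pass discarding residuals above 20 % of the fitted radius. The
sphere fit is the linearized (Kåsa) least-squares solution — exact on clean
spherical samples and deterministic; a rank check rejects coplanar input.

The three view planes all pass through the CoR:

* **frontal** — oriented by the total-least-squares plane of the acetabular
  rim samples (normal sign-aligned with the anatomical lateral axis);
* **sagittal** — contains the in-rim superior direction and the frontal
  normal (the superior–inferior rim chord, "12 and 18 o'clock");
* **axial** — contains the in-rim anterior direction and the frontal normal
  (the anterior–posterior rim chord, "9 and 15 o'clock").

The clock positions are read as a 12-hour dial with afternoon hours
(12 = superior, 18 ≡ 6 = inferior, 15 ≡ 3 and 9 = the horizontal positions).
In-plane coordinate axes are anatomical — (anterior, superior) in the frontal
view, (lateral, superior) sagittal, (anterior, medial) axial — so left- and
right-side specimens produce identical sector layouts without an explicit
re-mirroring step, and all three planes are exactly mutually orthogonal by
construction.

Eight sectors are angular wedges around the in-plane CoR, bounded by reference
rays toward landmark projections: frontal PS-F/SS-F/AS-F (acetabular-notch
aspects, ischiatic notch, ASIS), sagittal SS-S/MS-S (superior rim point,
ischiatic notch, and the caudal extension of the superior-rim ray), axial
PS-A/MS-A/AS-A (posterior/anterior rim extremes, superior pubic ramus,
ischiatic spine). The line→landmark and line→sector assignments follow the
published definitions literally; the implementation validates that the four
rays of a plane occur in consistent circular order and raises a
degenerate-sector error otherwise (also when two rays fall within 1° or a
landmark projects onto the CoR — an error, never a guess).

**3. Analysis.** Sector polygons are fans from the CoR: the two bounding rays
plus a radial third side sampled at the ray-fan resolution (default 1°,
shared between native and defected polygons). The third side is:

* native frontal: the rim samples projected into the frontal plane,
  interpolated periodically in polar angle;
* native sagittal/axial: the first crossing of the native mesh section
  contour along each ray (the bone boundary seen in the section);
* defected: per angular bin, the furthest *defect-border candidate* replaces
  the native third side when it lies beyond it. A pathological surface point
  (projected vertex in the frontal view, section-contour point in the section
  views) is a candidate when its 3D distance to the mirrored native surface
  exceeds δ.

Polygon vertices for defected bins sit on the furthest border *points
themselves* (their actual angle and radius), not on the bin's central ray;
the first and last vertices stay exactly on the bounding reference lines.
This keeps the defected polygon an (approximately) unbiased trace of the
defect border: snapping the per-bin maximum radius onto the central ray
systematically overestimates areas wherever the border radius changes quickly
within a bin. Intact sectors reproduce the native polygon exactly, so a
defect-free specimen yields AIR ≡ 0.

Areas are absolute shoelace sums (simple-polygon validity checked via
shapely); AIR = (A_def/A_nat − 1)×100 with grades minimal [0, 20],
moderate (20, 50], severe (50, 100], massive (100, ∞). Boundary values fall
into the lower category; this reading reproduces all published cohort counts.
Negative AIR (noise making the defected polygon marginally smaller) is clamped
to zero for grading only; the raw value is reported. A sector is flagged
*unmeasurable* — a flag, not an error — when pathological geometry is present
along fewer than half of its rays.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `delta_mm` | 2.0 mm | distance from the mirrored native surface beyond which a pathological point is a defect border; well above segmentation/mirroring noise (≈0.3 mm surface noise, sub-mm mirroring error) and well below clinically relevant border displacements (several mm) |
| `ray_step_deg` | 1° | ray-fan resolution of all sector polygons |
| `min_coverage` | 0.5 | minimum fraction of rays with pathological geometry before the unmeasurable flag |

**Coupling.** The ray fan must not be finer than the angular density of the
measured surface points: an empty bin falls back to the native radius, so an
overly fine fan under-counts defects. With δ-filtered candidates every ~1°
(the synthetic default), 1° is the finest safe fan; convergence studies must
tighten mesh sampling and fan together.

## The synthetic world

`acetair.synthetic` generates paired specimens whose ground truth is known in
closed form, so every pipeline stage is testable without patient data:

* The acetabulum is a hemispherical cup of radius R = rim diameter / 2
  (cohort diameters 52–66 mm, matching the reported specimen range), opening
  laterally, continued 4° past the rim plane so section contours extend
  beyond the sector-boundary rays. Hip centres sit ±85 mm from the midline;
  ASIS/pubic-tubercle positions make the mirror plane exactly x = 0 and the
  anatomical frame exactly axis-aligned. Sector-defining landmarks sit at
  parameterized positions that realize the published wedge layout
  (e.g. axial wedges PS-A 45°, MS-A 65°, AS-A 70°).
* A defect radially enlarges the cup surface by a factor f ≥ 1 within a
  target sector's wedge (a `coverage` fraction of its span, positioned inside
  it) and an out-of-plane band (±12° by default) around the sector's view
  plane — directly instantiating the "furthest border" semantics. The
  own-sector ground truth approaches coverage·(f²−1)·100 AIR points.
* Ground truth is computed by an analytic oracle independent of the pipeline:
  per view plane a dense (0.05° bins) radial profile is assembled from the
  ideal geometry — exact section curves of the deformed patches in the
  section planes, dense-sampled projections in the frontal view — and sector
  areas follow by quadrature of ½∫ρ²dθ. The oracle captures cross-plane
  spill-over (a large defect in one plane bulges another plane's profile), so
  pipeline and truth describe the same world. Defect regions must be pairwise
  disjoint; overlapping regions are rejected at generation time, because the
  composed deformation would have no clean closed-form truth.
* Optional Gaussian surface noise is applied along the radial direction
  (σ = 0 by default for exactness tests; 0.3 mm in robustness tests,
  approximating segmentation jitter). Factors below ≈1.1 at typical radii
  displace the surface by less than the default δ = 2 mm and are by design
  invisible to the pipeline.

What the generator does **not** emulate: realistic pelvic shape (iliac wing,
obturator foramen, cortical/cancellous structure), bilateral asymmetry of
healthy anatomy, segmentation artifacts near metal implants, and manual
landmark placement error beyond isotropic noise. A green synthetic test
therefore establishes the correctness of the geometry and measurement chain,
not clinical validity on real CT data.

The default six-specimen cohort mirrors the structure of the reported cohort:
one intact specimen, medially dominant and multi-sector patterns, left and
right pathological sides, and ground-truth AIR values spanning all four
grades.

## Numerical choices

* Mesh–plane cross-sections intersect faces against the exact plane; vertices
  lying exactly on it get their signed distance nudged by +1e-9 mm, so each
  crossing face contributes exactly one segment and contours are reproducible
  bit-for-bit. Ray–segment hit tests accept a small parameter slack (1e-6) so
  rays passing through nudge-split shared endpoints are not lost.
* STL files are parsed directly (ASCII and binary); per-facet duplicate
  vertices are merged exactly. Degenerate (zero-area) faces are dropped with
  a logged count.
* The published reference table is stored as packaged CSV with two editorial
  normalizations: one decimal-comma typo read as 136.47, and one
  trailing-zero padding (58.4 → 58.40). In-grade AIR ranges are always
  computed from data, never copied from prose.
* All coordinates are millimetres; no unit autodetection.

## Known limitations

* Defect detection reduces to a single distance threshold δ against the
  mirrored native surface; osteophytes (bone *gain*) beyond δ would also be
  flagged as borders. The reference procedure resolves such cases visually.
* The frontal view measures an orthogonal projection; whether the reference
  procedure measures the projection or the 3D rim-plane curve is not stated,
  and the projection was adopted.
* Sectors whose reference rays are not in circular order (possible with
  strongly distorted anatomy or unusual landmark placements) are rejected
  rather than reordered.
* Point-to-surface distances use nearest mesh vertices, adequate at the
  sub-millimetre vertex spacing of typical segmented meshes but biased for
  very coarse meshes.
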