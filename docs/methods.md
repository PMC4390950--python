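# Methods

`femplan` implements a computational model of femoral component planning
in total knee arthroplasty (TKA): given a watertight surface mesh of a
femur (millimetres), it locates the alignment axes and anterior cortex
landmarks a surgeon uses, places a femoral component by anterior
referencing, sizes it against mediolateral fit thresholds, and measures
the bone that the five cuts would remove.

## Axes and frames

All directions are unit vectors; ML points medial→lateral, AP
posterior→anterior, PD distal→proximal; the working frame is
right-handed (left femurs are mirrored in and the outputs mirrored back).

A *provisional* frame is detected from the mesh alone: PD is the first
principal component of the vertices, oriented so the wider (condylar)
end is distal; ML is the principal spread of the distal 15 % band; the
AP sign comes from the posterior condylar mass in the most distal 12 mm.
Landmarks found in this frame define the *mechanical* frame — origin at
the knee centre, PD along MA-1, ML along the TEA — and the extremal
landmarks are then re-taken in that frame (one refinement pass), so
results do not depend on the provisional long-axis tilt.

* **Condylar landmarks.** The condyles are split at the median ML
  coordinate of the distal band (32 mm proximal of the most distal
  point). Posterior / distal / anterior extremes and the epicondylar ML
  extremes are taken per condyle. Extremes on a tessellated surface are
  *plateau-averaged*: all vertices within 0.5 mm of the extreme are
  averaged, which suppresses the arbitrary-argmax jitter of a faceted
  surface.
* **TEA, PCA.** Lines through the epicondylar and posterior-condylar
  extremes. **PCA+3** rotates the PCA direction by exactly 3° about the
  axis perpendicular to it in the PCA–PD plane, in the external
  direction (towards the TEA). A literal rotation about PD would change
  the PCA↔PCA+3 angle by the cosine-squared of the PD component, so the
  perpendicular-axis construction is used to keep the 3° invariant
  exact.
* **Head centre.** An algebraic sphere fit seeded on the proximal 25 mm
  cap and grown by residual (|r| < max(1 mm, 2·RMS), six rounds). Gates:
  RMS ≤ 1 mm, radius 15–45 mm, inlier support, and *pole coverage* —
  a genuine head covers the proximal pole of its fitted sphere, a
  shaft/neck fit does not. Failing the gates raises a landmark error
  (e.g. on a distal-half mesh).
* **DAA.** Cross-sections perpendicular to the provisional long axis
  every 2 mm; the shaft is the longest contiguous run of sections with
  area ≤ 1.5× the median (the condylar flare and head exceed this;
  sections straddling the flare boundary are additionally trimmed until
  the area settles). A total-least-squares line through the centroids of
  the distal third of that run is the DAA, the virtual intramedullary
  guide. The 1.5× gate (rather than a looser one) is needed because the
  tail of the anterior flare otherwise leaks one or two sections into
  the fit and tilts it by a few tenths of a degree.
* **Knee centre.** The patellar groove plane is a total-least-squares
  plane through the sulcus polyline: on transverse sections across the
  trochlear span (−2 mm to +13 mm relative to the posterior condylar
  level) the deepest interior minimum of the anterior envelope between
  the condylar peaks is the sulcus point; one robust re-fit rejects
  sections that caught a spurious dip. The knee centre is the TEA
  intersected with this plane. MA-1 joins the head centre to it; MA-2
  joins the head centre to the DAA's distal exit point (first surface
  crossing of the DAA walking distally).

**FE/VV decomposition.** The flexion/extension component of the angle
between two axes is the signed angle between their sagittal-plane
projections (plane normal ML), flexion positive; varus/valgus likewise
in the coronal plane (normal AP), valgus positive (proximal end more
lateral). Unsigned magnitudes are reported alongside the signed values,
since published tables usually do not state the sign convention.

## Anterior cortex points

The lateral anterior ridge is traced over transverse sections 17–33 mm
proximal of the posterior condylar level: per section the most anterior
surface point lateral of the sulcus, plateau-averaged; a second pass
restricts to a ±6 mm ML band around the first pass' median so nearby
anterior shaft cortex can never capture the pick. The polyline is
resampled at 0.5 mm arclength and its AP signal smoothed with a 5 mm
moving average.

* **Sizing point** — the first (most distal) convex→concave inflection
  of the smoothed signal, located by the sign change of the second
  difference with a consistency window on either side; degenerate
  profiles (monotone, strictly convex) raise a no-saddle error.
* **FRAC point** — every profile sample between the ridge low point
  (minimum AP height in the search span) and the ridge high point is
  tried as the anterior reference: the flange plane is placed through
  it, and notch depth, anterior undercut area (flange area unsupported
  by bone) and the AP balance metric |mean anterior thickness − flange
  thickness| are recorded. The most posterior notch-free candidate is
  the FRAC point; if none is notch-free the minimal-depth candidate is
  returned with a warning. The full candidate trace is exposed so the
  balance/undercut trade-off can be audited rather than folded into an
  opaque objective.

The pipeline runs one fixed-point pass: initial size from the sizing
point's AP height → FRAC with that size → size re-selected from the
FRAC AP height → threshold refinement (re-running the FRAC search per
candidate size).

## Placement, sizing, resection

The component pose is fully constrained by the protocol: distal cut
perpendicular to the chosen longitudinal axis (MA-1, MA-2 or DAA),
10 mm proximal of the most distal femoral surface — the bony most-distal
point pushed 1.8 mm further distal to stand in for the absent cartilage,
so 8.2 mm of *bone* is resected at the most distal condyle on a
cartilage-free model; implant ML axis along the rotational reference
(PCA, PCA+3 or TEA) projected perpendicular to the longitudinal axis
(0° added rotation/flexion/varus); anterior flange plane through the
chosen cortex reference point; posterior and chamfer cuts rigid from the
implant geometry (anterior referencing). Mediolaterally the component is
centred on the distal cut contour.

*Fit.* Each cut plane is intersected with the mesh by exact
triangle–plane intersection; segments are chained into closed loops with
a 1e-6 mm union-find tolerance and flattened into the plane's 2D basis
(holes resolved by containment parity). Overhang and underhang are the
*mediolateral extent* mismatches between the bone and implant footprints
on the distal cut — implant edge beyond the bone silhouette is overhang,
bone beyond the implant is underhang. Anterior/posterior boundary
mismatches are summarised per zone but do not drive sizing: on the
anterior cut the flange top always extends past the narrowing ridge
(air above the cortex, not overhang), and the posterior cut's distal
band is covered by the chamfer. Thresholds: step one size down while
overhang > 1.5 mm, else one size up while underhang > 2 mm, visiting
each size at most once; if no size satisfies both, the visited size with
overhang within threshold and minimal overhang wins (overhang priority)
and the result is flagged.

*Thicknesses.* Resected thickness is the distance from each cut plane to
the corresponding condylar landmark along the plane normal (zero when
the landmark is on the retained side): FACL/FACM at the anterior
condylar prominences, FPCL/FPCM at the posterior extremes, FDCL/FDCM at
the distal extremes. The landmark convention (rather than a per-region
maximum) is chosen for reproducibility and is visible in the report.

*Notching.* Surface vertices up to 20 mm proximal of the flange's
proximal edge are tested for penetration anterior of the flange plane;
penetration beyond a 0.05 mm gate (numerical noise floor of the
tessellation) is a notch.

## Synthetic femur

Real planning inputs are CT segmentations; the package instead generates
parametric femur-like solids so every stage is testable against exact
ground truth. The bone is an implicit union — head sphere, neck capsule,
laterally and anteriorly bowed shaft tube, metaphyseal cone, two
condylar spheres (the medial one a few millimetres more distal, so the
distal cut removes more medial than lateral bone under a valgus
mechanical axis, as in vivo), epicondylar and anterior-condylar
prominences, an anterior flange slab with a carved trochlear groove, and
a crowned lateral ridge — polygonised by marching cubes (1.2 mm voxels
by default), which guarantees a watertight manifold. Ground-truth
landmarks are support points of the analytic primitives along the
mechanical-frame directions, computed by a small fixed-point iteration
because the frame itself depends on the landmarks.

The ridge's AP profile is a smoothstep drop (one inflection — the
closed-form sizing point) from the ridge high point to the low point,
followed by a proximal re-rise onto the shaft (the ridge's continuation,
an anterior tubercle). That tubercle sits proximal of the flange top, so
an anterior cut referenced at the *lowest* ridge point notches it, while
the FRAC search finds the lowest clearance point — reproducing the
clinical rationale for the FRAC point. Default dimensions describe an
adult femur (bone length ≈ 450 mm, head radius 24 mm, bicondylar width
≈ 81 mm, 5.4° epicondylar twist, 127° neck angle); cohorts jitter these
within anatomically plausible ranges under a seeded RNG, so runs are
reproducible.

What the generator does **not** emulate: population shape statistics
(no statistical atlas), cortical/trabecular interior, cartilage,
osteophytes or pathology, and the fine texture of real cortical bone.
Passing tests therefore demonstrate correctness of the geometry engine
and the protocol logic under known truth — not clinical validity on
patient anatomy.

## Numerical choices

* Landmark plateau tolerance 0.5 mm (0.3 mm on the ridge), matched to
  the ~1.2 mm tessellation edge length.
* Contour chaining tolerance 1e-6 mm; contours snapped exactly onto
  their plane after chaining.
* Sphere fits are algebraic (linear least squares); line/plane fits are
  total least squares via SVD; degenerate configurations (coplanar
  sphere points, collinear plane points, axis parallel to a projection
  normal) raise typed errors rather than returning garbage.
* Ties in size selection go to the smaller size (downsizing bias is the
  safer failure mode given the asymmetric 1.5/2 mm thresholds).
* Voxel pitch is capped at 2 mm: coarser grids cannot resolve the
  trochlear groove walls and the surface stops being manifold.
* Problem sizes: the test cohort uses 20 seeded femurs (~50k vertices
  each); the acceptance script summarises 12. These sizes give stable
  statistics for the angle summaries while keeping a full run in the
  minutes range.

## Known limitations

* The generic implant family is a stand-in: proprietary femoral
  component geometries differ in footprint shape and cut proportions, so
  absolute thickness/fit values are not comparable across systems.
* Posterior referencing and gap balancing are out of scope; only
  anterior referencing is modelled.
* Thickness is a point measurement at landmarks, not a resected-volume
  or per-region maximum.
* The left-femur path mirrors through the right-handed convention; the
  reported frame for a left femur is anatomically labelled (ML still
  medial→lateral) and therefore left-handed in world coordinates.
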