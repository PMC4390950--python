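# femplan

Automated femoral planning for total knee arthroplasty (TKA) on 3D
surface meshes: alignment axes, anterior-cortex landmarks, implant
placement, sizing and resection analysis.

Given a watertight femur surface (STL/PLY/OBJ, millimetres) the package
computes, the way a planning workstation would:

* the **alignment axes** — transepicondylar axis (TEA), posterior
  condylar axis (PCA) and PCA+3° of external rotation, the distal
  anatomic axis (DAA, a virtual intramedullary guide: total-least-squares
  line through the distal-third shaft centroids), and two mechanical
  axes: **MA-1** (femoral head centre → knee centre, where the knee
  centre is the TEA intersected with the patellar groove plane) and
  **MA-2** (head centre → distal exit point of the DAA);
* the **anterior cortex points** on the lateral ridge — the *sizing
  point* (the saddle where the anterior profile turns from convex to
  concave, what a surgical sizing guide lands on) and the *FRAC point*
  (femoral resection anterior cortex point): the most posterior point on
  the ridge whose anterior flange plane does not notch the cortex
  proximal to the flange;
* an **anterior-referenced implant placement**: distal cut ⟂ the chosen
  longitudinal axis, 10 mm proximal of the most distal femoral surface
  (with a 1.8 mm virtual-cartilage offset), rotation set by PCA / PCA+3
  / TEA, anterior flange pinned to the chosen cortex point;
* **sizing** from the bone's AP height, refined against mediolateral
  footprint fit with 1.5 mm overhang / 2 mm underhang thresholds;
* the **resected-bone thicknesses** (FACL, FPCL, FACM, FPCM, FDCL,
  FDCM: anterior/posterior/distal × lateral/medial), footprint
  overhang/underhang, and a notching check.

Because clinical CT segmentations cannot be shipped, the package also
contains a first-class synthetic femur generator (`femplan.synthetic`)
that builds watertight femur-like surfaces with closed-form ground-truth
landmarks; the whole pipeline is tested against that truth. A generic
parametric implant family stands in for proprietary component
geometries. See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from femplan.synthetic import FemurParams, generate_femur
from femplan.implant import generate_generic_family
from femplan.placement import PlacementConfig
from femplan.report import plan

mesh, truth = generate_femur(FemurParams())      # canonical right femur
family = generate_generic_family()               # 7 sizes, AP 40-64 mm
report = plan(mesh, family, PlacementConfig())   # MA-1 / PCA+3 / FRAC

print(report.angles)
print("final size:", report.final_size)
print(report.thicknesses)
print(report.notch)
```

prints

```
{'pca_tea': 6.913, 'ma1_daa_fe': 1.319, 'ma1_daa_vv': 6.284,
 'ma1_ma2_fe': 1.66, 'ma1_ma2_vv': 0.61, 'signed': {...}}
final size: 3
{'FACL': 12.344, 'FPCL': 12.133, 'FACM': 12.881, 'FPCM': 10.065,
 'FDCL': 6.566, 'FDCM': 8.2, 'total_lateral': 24.477, 'total_medial': 22.947}
{'notched': False, 'notch_depth': 0.0}
```

Reading this: the PCA and TEA differ by ~6.9° on this anatomy; MA-2 is
~1.7° more flexed than MA-1 (its exit point lies anterior of the knee
centre); size 3 (AP 48 mm) was chosen and kept, its distal cut removes
8.2 mm of bone at the most distal (medial) condyle — exactly the 10 mm
protocol offset minus the 1.8 mm cartilage allowance — and the
FRAC-referenced anterior cut leaves the anterior cortex un-notched.

The same pipeline is scriptable from the shell:

```sh
femplan synth --seed 7 --out /tmp/femur          # synthetic fixture + truth
femplan family --out /tmp/family.json            # generic implant family
femplan plan --mesh /tmp/femur.stl --family /tmp/family.json --out /tmp/plan
femplan compare --mesh /tmp/femur.stl --family /tmp/family.json --axes MA1,MA2
```

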