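# Implant family JSON schema (version 1)

An implant family file describes the sizes of one femoral-component
system in the implant-local frame: origin at the distal-cut centroid,
+x medial→lateral, +y posterior→anterior, +z distal→proximal, units mm.
Cut-plane normals point into the retained bone.

```json
{
 "schema_version": 1,
 "name": "generic-8",
 "sizes": [
  {
   "label": "1",
   "ap_height": 40.0,          // outer anteroposterior size
   "ml_width": 60.0,           // mediolateral width of the distal cut
   "flange_thickness": 4.0,    // metal anterior of the anterior cut
   "posterior_thickness": 8.0, // metal posterior of the posterior cut
   "distal_thickness": 9.0,
   "flange_span": 34.0,        // local z of the flange's proximal edge
   "anterior_offset": 14.0,    // y of the anterior flange plane
   "posterior_cut_y": -14.0,   // y of the posterior cut plane
   "chamfer_z_anterior": 8.8,  // z where the 45° anterior chamfer meets the flange
   "chamfer_z_posterior": 4.8,
   "footprints": {
    "distal":            [[u, v], ...],   // closed polygon, plane coords
    "anterior":          [[u, v], ...],
    "posterior":         [[u, v], ...],
    "anterior_chamfer":  [[u, v], ...],
    "posterior_chamfer": [[u, v], ...]
   }
  }
 ]
}
```

Rules enforced by the loader (`femplan.implant.load_family`):

* `schema_version` must equal 1;
* at least 3 sizes, with strictly increasing `ap_height`;
* each footprint is a closed, non-self-intersecting polygon in the
  coordinates of its cut plane (u = ML; v = AP on the distal cut, local
  z on the others);
* the five cut planes are reconstructed from the scalar fields above as
  a closed sagittal box profile (distal cut at z = 0, 45° chamfers).

`femplan.implant.generate_generic_family` writes this schema;
`femplan family --out family.json` does so from the shell. The packaged
8-size family lives at `src/femplan/data/generic_family.json`.
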