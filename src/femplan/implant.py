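"""Generic femoral-component families: sizes, cut geometry, footprints.

Commercial implant geometries are proprietary, so the package ships a
configurable *generic* family: a ladder of sizes with linearly spaced AP
heights, a five-plane cut profile (distal, anterior, posterior and two
45-degree chamfers) and rounded bicondylar footprints that scale with
size.  Families can also be loaded from a JSON schema so real geometry
can be dropped in.

Implant-local frame: origin at the distal-cut centroid; +x medial to
lateral, +y posterior to anterior, +z distal to proximal.  Cut-plane
normals point *into* the retained implant/bone side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .geometry import Plane

__all__ = [
    "ImplantSize",
    "ImplantFamily",
    "ImplantSchemaError",
    "generate_generic_family",
    "load_family",
    "save_family",
    "select_initial_size",
]

SCHEMA_VERSION = 1

#: names of the five cuts in sagittal order, distal first
CUT_NAMES = ("distal", "anterior", "posterior", "anterior_chamfer", "posterior_chamfer")


class ImplantSchemaError(ValueError):
    """Implant family file violates the schema."""


@dataclass
class ImplantSize:
    """One size of a femoral component (all dimensions mm).

    ``cut_planes`` maps cut name -> Plane in the implant-local frame with
    the in-plane basis (u, v) that footprints are expressed in.
    ``footprints`` maps cut name -> closed 2D polygon (list of [u, v]).
    """

    label: str
    ap_height: float
    ml_width: float
    flange_thickness: float
    posterior_thickness: float
    distal_thickness: float
    flange_span: float
    anterior_offset: float      # y of the anterior flange plane
    posterior_cut_y: float      # y of the posterior cut plane
    chamfer_z_anterior: float   # z where the anterior chamfer meets the flange
    chamfer_z_posterior: float
    cut_planes: dict = field(default_factory=dict)
    footprints: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.ap_height <= 0 or self.ml_width <= 0:
            raise ImplantSchemaError(f"size {self.label}: non-positive dimensions")
        for name in CUT_NAMES:
            if name not in self.cut_planes:
                raise ImplantSchemaError(f"size {self.label}: missing cut plane {name}")
        for name, poly in self.footprints.items():
            p = Polygon(poly)
            if not p.is_valid:
                raise ImplantSchemaError(f"size {self.label}: footprint {name} self-intersects")

    def footprint_polygon(self, cut: str) -> Polygon:
        return Polygon(self.footprints[cut])


@dataclass
class ImplantFamily:
    name: str
    sizes: list[ImplantSize]

    def validate(self) -> None:
        if len(self.sizes) < 3:
            raise ImplantSchemaError("a family needs at least 3 sizes")
        aps = [s.ap_height for s in self.sizes]
        if any(b <= a for a, b in zip(aps, aps[1:])):
            raise ImplantSchemaError("AP heights must be strictly increasing")
        for s in self.sizes:
            s.validate()


# --------------------------------------------------------------------------
# generic family construction


def _sagittal_profile(ap: float, flange: float, posterior: float):
    """Key y/z stations of the five-cut box profile for one size."""
    a = 0.35 * ap                      # anterior flange plane
    p = a + flange + posterior - ap    # posterior cut plane
    z_a = 0.22 * ap                    # anterior chamfer / flange junction
    z_p = 0.12 * ap
    return a, p, z_a, z_p


def _make_cut_planes(a: float, p: float, z_a: float, z_p: float) -> dict:
    """Five planes, inward normals, with footprint bases (u = ML).

    The chamfers run at 45 degrees between the distal cut and the
    anterior/posterior cuts respectively.
    """
    ex = np.array([1.0, 0.0, 0.0])
    s2 = 1.0 / np.sqrt(2.0)
    return {
        "distal": Plane(origin=[0, 0, 0], normal=[0, 0, 1], u=ex, v=[0, 1, 0]),
        "anterior": Plane(origin=[0, a, z_a], normal=[0, -1, 0], u=ex, v=[0, 0, 1]),
        "posterior": Plane(origin=[0, p, z_p], normal=[0, 1, 0], u=ex, v=[0, 0, 1]),
        "anterior_chamfer": Plane(origin=[0, a - z_a, 0], normal=[0, -s2, s2],
                                  u=ex, v=[0, s2, s2]),
        "posterior_chamfer": Plane(origin=[0, p + z_p, 0], normal=[0, s2, s2],
                                   u=ex, v=[0, -s2, s2]),
    }


def _rounded_rect(w: float, h: float, cy: float, r: float) -> Polygon:
    return box(-w / 2, cy - h / 2, w / 2, cy + h / 2).buffer(r, quad_segs=4)


def _distal_footprint(ml: float, y1: float, y2: float) -> list:
    """Bicondylar distal cut: two condylar discs and an anterior bridge.

    The condylar pads are discs (matching the near-circular cut surface
    of a condyle) whose outer edges reach +-ml/2; everything is clipped
    to the distal-cut strip between the two chamfer junctions.
    """
    from shapely.geometry import Point

    span = y1 - y2
    r = 0.23 * ml
    cv = y2 + 0.2 * span
    pads = [Point(s * (ml / 2 - r), cv).buffer(r, quad_segs=12) for s in (-1, 1)]
    bridge = box(-0.28 * ml, cv, 0.28 * ml, y1)
    strip = box(-ml / 2, y2, ml / 2, y1)
    poly = unary_union(pads + [bridge]).intersection(strip).simplify(0.05)
    return [[round(c[0], 3), round(c[1], 3)] for c in poly.exterior.coords]


def _make_footprints(size_args: dict) -> dict:
    ml = size_args["ml_width"]
    a, p = size_args["anterior_offset"], size_args["posterior_cut_y"]
    z_a, z_p = size_args["chamfer_z_anterior"], size_args["chamfer_z_posterior"]
    y1, y2 = a - z_a, p + z_p
    span_fl = size_args["flange_span"]
    flange_w = 0.70 * ml
    # anterior cut coords: u = ML, v = z along the flange
    flange = _rounded_rect(flange_w - 4, span_fl - z_a - 4, (span_fl + z_a) / 2, 2.0)
    paddle_w = 0.42 * ml
    post_h = 0.55 * size_args["ap_height"] - z_p
    from shapely import affinity

    post_m = affinity.translate(_rounded_rect(paddle_w - 4, post_h, z_p + post_h / 2, 2.0),
                                xoff=-(ml / 2 - paddle_w / 2))
    post_l = affinity.translate(_rounded_rect(paddle_w - 4, post_h, z_p + post_h / 2, 2.0),
                                xoff=ml / 2 - paddle_w / 2)
    cham_a = _rounded_rect(flange_w - 4, z_a * np.sqrt(2) - 2, z_a * np.sqrt(2) / 2, 1.0)
    cham_p = _rounded_rect(0.8 * ml - 4, z_p * np.sqrt(2) - 2, z_p * np.sqrt(2) / 2, 1.0)

    def coords(poly):
        return [[round(c[0], 3), round(c[1], 3)] for c in poly.exterior.coords]

    return {
        "distal": _distal_footprint(ml, y1, y2),
        "anterior": coords(flange),
        "posterior": coords(unary_union([post_m, post_l]).convex_hull),
        "anterior_chamfer": coords(cham_a),
        "posterior_chamfer": coords(cham_p),
    }


def _build_size(label: str, ap: float, aspect: float) -> ImplantSize:
    flange, posterior, distal = 4.0, 8.0, 9.0
    a, p, z_a, z_p = _sagittal_profile(ap, flange, posterior)
    args = dict(
        label=label, ap_height=ap, ml_width=aspect * ap,
        flange_thickness=flange, posterior_thickness=posterior,
        distal_thickness=distal, flange_span=0.85 * ap,
        anterior_offset=a, posterior_cut_y=p,
        chamfer_z_anterior=z_a, chamfer_z_posterior=z_p,
    )
    size = ImplantSize(**args, cut_planes=_make_cut_planes(a, p, z_a, z_p),
                       footprints=_make_footprints(args))
    size.validate()
    return size


def generate_generic_family(ap_min: float = 40.0, ap_max: float = 64.0,
                            n_sizes: int = 7, aspect: float = 1.5,
                            name: str = "generic") -> ImplantFamily:
    """Parametric stand-in family with evenly spaced AP heights."""
    if not (ap_min < ap_max) or n_sizes < 3:
        raise ImplantSchemaError("need ap_min < ap_max and at least 3 sizes")
    aps = np.linspace(ap_min, ap_max, n_sizes)
    fam = ImplantFamily(
        name=name,
        sizes=[_build_size(str(i + 1), float(ap), aspect) for i, ap in enumerate(aps)],
    )
    fam.validate()
    return fam


# --------------------------------------------------------------------------
# serialization


def save_family(family: ImplantFamily, path: str | Path) -> None:
    data = {
        "schema_version": SCHEMA_VERSION,
        "name": family.name,
        "sizes": [
            {
                "label": s.label,
                "ap_height": s.ap_height,
                "ml_width": s.ml_width,
                "flange_thickness": s.flange_thickness,
                "posterior_thickness": s.posterior_thickness,
                "distal_thickness": s.distal_thickness,
                "flange_span": s.flange_span,
                "anterior_offset": s.anterior_offset,
                "posterior_cut_y": s.posterior_cut_y,
                "chamfer_z_anterior": s.chamfer_z_anterior,
                "chamfer_z_posterior": s.chamfer_z_posterior,
                "footprints": s.footprints,
            }
            for s in family.sizes
        ],
    }
    Path(path).write_text(json.dumps(data))


def load_family(path: str | Path) -> ImplantFamily:
    """Load and validate an implant family from its JSON schema."""
    try:
        data = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ImplantSchemaError(f"cannot read implant family {path}: {exc}") from exc
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ImplantSchemaError(
            f"unsupported schema version {data.get('schema_version')!r}")
    sizes = []
    for s in data.get("sizes", []):
        try:
            planes = _make_cut_planes(s["anterior_offset"], s["posterior_cut_y"],
                                      s["chamfer_z_anterior"], s["chamfer_z_posterior"])
            sizes.append(ImplantSize(cut_planes=planes, **s))
        except (KeyError, TypeError) as exc:
            raise ImplantSchemaError(f"malformed size entry: {exc}") from exc
    fam = ImplantFamily(name=data.get("name", "unnamed"), sizes=sizes)
    fam.validate()
    return fam


def packaged_family() -> ImplantFamily:
    """The generic 8-size family shipped with the package."""
    from importlib.resources import files

    return load_family(str(files("femplan").joinpath("data", "generic_family.json")))


# --------------------------------------------------------------------------
# size selection


def select_initial_size(bone_ap: float, family: ImplantFamily) -> tuple[ImplantSize, bool]:
    """Size with the closest AP height; ties go to the smaller size.

    Returns (size, out_of_range): out_of_range is set when the bone AP
    falls outside the family's AP span and the extreme size was clamped.
    """
    if not family.sizes:
        raise ImplantSchemaError("empty implant family")
    best = min(family.sizes, key=lambda s: (abs(s.ap_height - bone_ap), s.ap_height))
    out = not (family.sizes[0].ap_height <= bone_ap <= family.sizes[-1].ap_height)
    return best, out
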