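"""Anterior-referencing implant placement.

The component pose is fully determined by three rules that emulate the
standard surgical protocol with 0 degrees of added flexion/extension,
varus/valgus and internal/external rotation:

1. the distal cut is perpendicular to the chosen longitudinal axis
   (MA-1, MA-2 or DAA) and sits ``distal_offset`` (10 mm) proximal of the
   most distal femoral surface — the bony most-distal point pushed
   ``cartilage_offset`` (1.8 mm) further distal to stand in for the
   missing cartilage;
2. the implant ML axis is the rotational reference (PCA, PCA+3 or TEA)
   projected perpendicular to the longitudinal axis;
3. the anterior flange plane passes through the chosen anterior cortex
   reference point (FRAC, sizing point or ridge average); posterior and
   chamfer cuts follow rigidly from the implant geometry.

Mediolaterally the component is centred on the distal cut contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .geometry import Plane, unit

__all__ = [
    "PlacementConfig",
    "ResectionPlanes",
    "PlacementError",
    "apply_cartilage_offset",
    "build_resection_planes",
    "compute_bone_ap_height",
]


class PlacementError(RuntimeError):
    """No pose satisfies the placement constraints."""


@dataclass(frozen=True)
class PlacementConfig:
    """Planning configuration; defaults follow the standard protocol."""

    longitudinal_axis: str = "MA1"        # MA1 | MA2 | DAA
    rotation_reference: str = "PCA3"      # PCA | PCA3 | TEA
    distal_offset: float = 10.0           # mm proximal of the (cartilage) distal point
    cartilage_offset: float = 1.8         # mm of virtual distal cartilage
    overhang_threshold: float = 1.5       # mm
    underhang_threshold: float = 2.0      # mm
    anterior_reference: str = "FRAC"      # FRAC | SIZING | RIDGE_AVERAGE

    def __post_init__(self):
        if self.longitudinal_axis.upper() not in ("MA1", "MA2", "DAA"):
            raise ValueError(f"unknown longitudinal axis {self.longitudinal_axis!r}")
        if self.rotation_reference.upper() not in ("PCA", "PCA3", "PCA_PLUS3", "TEA"):
            raise ValueError(f"unknown rotation reference {self.rotation_reference!r}")
        if self.anterior_reference.upper() not in ("FRAC", "SIZING", "RIDGE_AVERAGE"):
            raise ValueError(f"unknown anterior reference {self.anterior_reference!r}")
        for name in ("distal_offset", "cartilage_offset",
                     "overhang_threshold", "underhang_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "PlacementConfig":
        return dc_replace(self, **kw)

    @classmethod
    def from_dict(cls, data: dict) -> "PlacementConfig":
        return cls(**{k: v for k, v in data.items() if k in cls.__dataclass_fields__})

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class ResectionPlanes:
    """The five cut planes in bone coordinates plus the implant pose."""

    distal: Plane
    anterior: Plane
    posterior: Plane
    anterior_chamfer: Plane
    posterior_chamfer: Plane
    implant_pose: np.ndarray          # 4x4, implant-local -> bone
    flange_proximal_pd: float         # PD coord (axes frame) of the flange top edge
    implant_label: str = ""

    def plane(self, name: str) -> Plane:
        return getattr(self, name)

    def to_dict(self) -> dict:
        def pl(p: Plane):
            return {"origin": p.origin.tolist(), "normal": p.normal.tolist(),
                    "u": p.u.tolist(), "v": p.v.tolist()}

        return {
            "planes": {n: pl(getattr(self, n)) for n in
                       ("distal", "anterior", "posterior", "anterior_chamfer", "posterior_chamfer")},
            "implant_pose": self.implant_pose.tolist(),
            "implant_label": self.implant_label,
            "flange_proximal_pd": self.flange_proximal_pd,
        }


def apply_cartilage_offset(most_distal_point: np.ndarray, axis, offset: float) -> np.ndarray:
    """Push the bony most-distal point distally to emulate cartilage.

    ``axis`` is the longitudinal axis with its direction pointing
    proximally; the virtual cartilage surface lies ``offset`` mm further
    distal along it.
    """
    if offset < 0:
        raise ValueError("cartilage offset must be non-negative")
    d = axis.direction if hasattr(axis, "direction") else unit(axis)
    return np.asarray(most_distal_point, float) - offset * d


def _distal_ml_center(mesh, plane: Plane) -> float:
    from .resection import flatten_contour, intersect_mesh_plane

    contour = intersect_mesh_plane(mesh, plane)
    if not contour.loops:
        raise PlacementError("distal cut plane misses the bone")
    fp = flatten_contour(contour)
    xs = np.vstack([np.asarray(p.exterior.coords) for p in fp.polygons])[:, 0]
    return float(0.5 * (xs.min() + xs.max()))


def build_resection_planes(mesh, axes, implant, anterior_ref_point, config: PlacementConfig,
                           ml_center: float | None = None) -> ResectionPlanes:
    """Pose the implant and express its five cut planes in bone coordinates.

    ``anterior_ref_point`` is the anterior cortex point the flange plane
    must contain.  ``ml_center`` can be supplied to skip re-sectioning the
    distal cut when many poses share the same longitudinal axis (e.g.
    during the FRAC search).
    """
    L = axes.axis(config.longitudinal_axis).direction
    if np.dot(L, axes.frame.PD) < 0:
        L = -L
    ref_dir = axes.axis(config.rotation_reference).direction
    if np.dot(ref_dir, axes.frame.ML) < 0:
        ref_dir = -ref_dir
    x_i = ref_dir - np.dot(ref_dir, L) * L
    if np.linalg.norm(x_i) < 1e-9:
        raise PlacementError("rotation reference parallel to longitudinal axis")
    x_i = unit(x_i)
    y_i = np.cross(L, x_i)
    R = np.column_stack([x_i, y_i, L])

    cart_point = apply_cartilage_offset(axes.most_distal_point, L, config.cartilage_offset)
    distal_origin = cart_point + config.distal_offset * L
    distal_plane = Plane(origin=distal_origin, normal=L, u=x_i, v=y_i)
    if ml_center is None:
        ml_center = _distal_ml_center(mesh, distal_plane)

    a = implant.anterior_offset
    # translation from the three scalar constraints: distal-cut height,
    # anterior flange through the reference point, ML centring
    t = (np.dot(distal_origin, L) * L
         + (np.dot(np.asarray(anterior_ref_point, float), y_i) - a) * y_i
         + (np.dot(distal_origin, x_i) + ml_center) * x_i)
    pose = np.eye(4)
    pose[:3, :3] = R
    pose[:3, 3] = t

    def world_plane(name: str) -> Plane:
        lp = implant.cut_planes[name]
        return Plane(origin=t + R @ lp.origin, normal=R @ lp.normal,
                     u=R @ lp.u, v=R @ lp.v)

    flange_top = t + R @ np.array([0.0, a, implant.flange_span])
    flange_pd = float((flange_top - axes.frame.origin) @ axes.frame.PD)
    return ResectionPlanes(
        distal=world_plane("distal"),
        anterior=world_plane("anterior"),
        posterior=world_plane("posterior"),
        anterior_chamfer=world_plane("anterior_chamfer"),
        posterior_chamfer=world_plane("posterior_chamfer"),
        implant_pose=pose,
        flange_proximal_pd=flange_pd,
        implant_label=implant.label,
    )


def compute_bone_ap_height(frame, anterior_reference_point, posterior_points) -> float:
    """AP extent from the anterior reference to the posterior condyles.

    Measured along the frame AP direction against the more posterior of
    the two posterior condylar points; this is the quantity matched
    against the implant AP height for initial size selection.
    """
    ap_ref = float((np.asarray(anterior_reference_point, float) - frame.origin) @ frame.AP)
    ap_post = min(float((np.asarray(p, float) - frame.origin) @ frame.AP)
                  for p in posterior_points)
    return ap_ref - ap_post
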