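"""Cut-plane analysis: contours, footprints, fit, sizing and notching.

The resection workflow mirrors what a planning workstation does: each
implant cutting plane is intersected with the bone to give a closed 3D
contour, the contour is flattened into the plane's 2D coordinates to form
the *bone footprint*, and that footprint is compared against the implant
footprint to quantify mediolateral overhang (implant beyond bone) and
underhang (bone beyond implant).  Those two numbers drive implant-size
refinement with clinical thresholds of 1.5 mm overhang and 2 mm
underhang.  Resected-bone thicknesses are read off at the condylar
landmark points, and anterior-cortex notching is detected by probing the
cortex proximal to the flange.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .geometry import Plane

__all__ = [
    "CutContour",
    "Footprint2D",
    "FitReport",
    "ResectionThicknesses",
    "NotchReport",
    "FootprintError",
    "intersect_mesh_plane",
    "flatten_contour",
    "compute_fit",
    "refine_size",
    "measure_thicknesses",
    "detect_notching",
]

#: chaining tolerance for intersection segments (mm)
CHAIN_TOL = 1e-6
#: penetration below this is numerical noise, not a notch (mm)
NOTCH_GATE = 0.05
#: implant boundary sampling step for fit evaluation (mm)
FIT_SAMPLE_STEP = 0.5


class FootprintError(RuntimeError):
    """No closed loop available to build a footprint."""


@dataclass
class CutContour:
    plane: Plane
    loops: list[np.ndarray] = field(default_factory=list)          # closed, first == last
    open_segments: list[np.ndarray] = field(default_factory=list)  # non-watertight leftovers


@dataclass
class Footprint2D:
    plane: Plane
    polygons: list[Polygon] = field(default_factory=list)  # CCW shells, holes resolved
    area: float = 0.0

    @property
    def union(self):
        return unary_union(self.polygons) if self.polygons else Polygon()

    @property
    def centroid(self) -> np.ndarray:
        c = self.union.centroid
        return np.array([c.x, c.y])


@dataclass
class FitReport:
    """Implant-vs-bone boundary fit on one cut plane.

    Positive sample distances are overhang (implant outside bone);
    underhang comes from bone-boundary samples outside the implant.  The
    reported maxima cover the medial and lateral zones only — the fit
    that drives sizing is mediolateral.  Anterior and posterior zones are
    still summarised (the bone contour legitimately extends past the
    implant strip there, into regions covered by the adjacent cuts).
    """

    max_overhang: float
    max_underhang: float
    zones: dict = field(default_factory=dict)  # zone -> {"overhang": .., "underhang": ..}
    samples: np.ndarray | None = None


@dataclass
class ResectionThicknesses:
    """Resected bone at the landmark points (mm).

    FACL/FACM: anterior cut, lateral/medial; FPCL/FPCM: posterior cut;
    FDCL/FDCM: distal cut.  Totals are anterior + posterior per side.
    """

    FACL: float
    FPCL: float
    FACM: float
    FPCM: float
    FDCL: float
    FDCM: float

    @property
    def total_lateral(self) -> float:
        return self.FACL + self.FPCL

    @property
    def total_medial(self) -> float:
        return self.FACM + self.FPCM

    def to_dict(self) -> dict:
        d = {k: round(getattr(self, k), 3) for k in ("FACL", "FPCL", "FACM", "FPCM", "FDCL", "FDCM")}
        d["total_lateral"] = round(self.total_lateral, 3)
        d["total_medial"] = round(self.total_medial, 3)
        return d


@dataclass
class NotchReport:
    notched: bool
    notch_depth: float
    notch_location: np.ndarray | None = None


# --------------------------------------------------------------------------
# contour extraction and flattening


def _merge_endpoints(points: np.ndarray, tol: float) -> np.ndarray:
    """Union-find merge of points closer than tol; returns label per point."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=tol, output_type="ndarray")
    parent = np.arange(len(points))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    return np.array([find(i) for i in range(len(points))])


def intersect_mesh_plane(mesh: trimesh.Trimesh, plane: Plane) -> CutContour:
    """Exact triangle-plane intersection chained into closed loops.

    On a watertight mesh every chain closes; open chains (non-watertight
    input) are returned separately in ``open_segments``.
    """
    segments = trimesh.intersections.mesh_plane(
        mesh, plane_normal=plane.normal, plane_origin=plane.origin)
    if len(segments) == 0:
        return CutContour(plane=plane)
    lengths = np.linalg.norm(segments[:, 0] - segments[:, 1], axis=1)
    segments = segments[lengths > CHAIN_TOL]
    if len(segments) == 0:
        return CutContour(plane=plane)
    pts = segments.reshape(-1, 3)
    labels = _merge_endpoints(pts, CHAIN_TOL)
    # adjacency between merged endpoint labels
    adj: dict[int, list[int]] = {}
    seen_edges = set()
    for i in range(len(segments)):
        a, b = labels[2 * i], labels[2 * i + 1]
        if a == b or (min(a, b), max(a, b)) in seen_edges:
            continue
        seen_edges.add((min(a, b), max(a, b)))
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    coord = {}
    for lbl, p in zip(labels, pts):
        coord.setdefault(lbl, p)

    loops, opens = [], []
    unused = set(seen_edges)

    def walk(start, nxt):
        chain = [start, nxt]
        while True:
            cand = [c for c in adj[chain[-1]]
                    if (min(chain[-1], c), max(chain[-1], c)) in unused]
            if not cand:
                break
            c = cand[0]
            unused.discard((min(chain[-1], c), max(chain[-1], c)))
            chain.append(c)
            if c == chain[0]:
                break
        return chain

    # start open chains at odd-degree nodes first, then close loops
    degrees = {k: len(v) for k, v in adj.items()}
    odd_nodes = [k for k, dg in degrees.items() if dg % 2 == 1]
    for start in odd_nodes:
        for nxt in list(adj[start]):
            e = (min(start, nxt), max(start, nxt))
            if e in unused:
                unused.discard(e)
                chain = walk(start, nxt)
                opens.append(np.array([coord[c] for c in chain]))
    while unused:
        a, b = next(iter(unused))
        unused.discard((a, b))
        chain = walk(a, b)
        arr = np.array([coord[c] for c in chain])
        if chain[0] == chain[-1] and len(chain) > 3:
            loops.append(arr)
        else:
            opens.append(arr)
    # snap chained points exactly onto the plane
    out_loops = []
    for lp in loops:
        d = (lp - plane.origin) @ plane.normal
        out_loops.append(lp - np.outer(d, plane.normal))
    return CutContour(plane=plane, loops=out_loops, open_segments=opens)


def flatten_contour(contour: CutContour) -> Footprint2D:
    """Map closed loops into plane coordinates and resolve hole nesting.

    Loop containment parity decides shells vs holes; all shells are
    oriented counter-clockwise and the area is the shell total minus
    holes.
    """
    if not contour.loops:
        raise FootprintError("contour has no closed loop")
    rings = []
    for lp in contour.loops:
        r2 = contour.plane.to_2d(lp)
        if len(r2) >= 4:
            rings.append(r2)
    if not rings:
        raise FootprintError("contour loops degenerate after flattening")
    raw = [Polygon(r) for r in rings]
    raw = [p if p.is_valid else p.buffer(0) for p in raw]
    order = np.argsort([-p.area for p in raw])
    shells, holes = [], []
    for k in order:
        p = raw[k]
        depth = sum(1 for j in order if j != k and raw[j].contains(p.representative_point()))
        (shells if depth % 2 == 0 else holes).append(p)
    polys = []
    for sh in shells:
        inner = [h for h in holes if sh.contains(h.representative_point())]
        poly = Polygon(sh.exterior.coords,
                       [h.exterior.coords for h in inner])
        polys.append(shapely.geometry.polygon.orient(poly, sign=1.0))
    return Footprint2D(plane=contour.plane, polygons=polys,
                       area=float(sum(p.area for p in polys)))


# --------------------------------------------------------------------------
# fit evaluation


def _boundary_samples(geom, step: float) -> np.ndarray:
    polys = list(geom.geoms) if hasattr(geom, "geoms") else [geom]
    out = []
    for p in polys:
        ring = p.exterior
        n = max(8, int(np.ceil(ring.length / step)))
        out.append(np.array([ring.interpolate(i / n, normalized=True).coords[0]
                             for i in range(n)]))
    return np.vstack(out)


def _zone_of(sample: np.ndarray, center: np.ndarray) -> str:
    u, v = sample - center
    if abs(u) >= abs(v):
        return "medial" if u < 0 else "lateral"
    return "anterior" if v > 0 else "posterior"


def compute_fit(bone: Footprint2D, implant_fp: Footprint2D,
                keep_samples: bool = False) -> FitReport:
    """Mediolateral overhang/underhang between bone and implant footprints.

    Both footprints must live in the same plane frame (u = medial to
    lateral, v = posterior to anterior).  The governing maxima compare
    the medial and lateral extents of the two footprints: overhang where
    the implant edge reaches beyond the bone silhouette on that side,
    underhang the other way round -- the mediolateral size mismatch that
    implant sizing acts on.  Anteroposterior coverage differences
    (regions handled by the adjacent cuts) are summarised per zone from
    boundary samples but do not enter the maxima.
    """
    bone_u = bone.union
    impl_u = implant_fp.union
    if bone_u.is_empty or impl_u.is_empty:
        raise FootprintError("empty footprint in fit evaluation")

    zones = {z: {"overhang": 0.0, "underhang": 0.0}
             for z in ("medial", "lateral", "anterior", "posterior")}
    records = []

    bu0, _, bu1, _ = bone_u.bounds
    iu0, _, iu1, _ = impl_u.bounds
    zones["medial"]["overhang"] = max(0.0, bu0 - iu0)
    zones["medial"]["underhang"] = max(0.0, iu0 - bu0)
    zones["lateral"]["overhang"] = max(0.0, iu1 - bu1)
    zones["lateral"]["underhang"] = max(0.0, bu1 - iu1)

    # anterior/posterior coverage summaries from boundary samples
    center = np.array([impl_u.centroid.x, impl_u.centroid.y])
    for s in _boundary_samples(impl_u, FIT_SAMPLE_STEP):
        d = float(Point(s).distance(bone_u))
        z = _zone_of(s, center)
        if z in ("anterior", "posterior"):
            zones[z]["overhang"] = max(zones[z]["overhang"], d)
        if keep_samples:
            records.append([s[0], s[1], d])
    for s in _boundary_samples(bone_u, FIT_SAMPLE_STEP):
        d = float(Point(s).distance(impl_u))
        z = _zone_of(s, center)
        if z in ("anterior", "posterior"):
            zones[z]["underhang"] = max(zones[z]["underhang"], d)
        if keep_samples:
            records.append([s[0], s[1], -d])

    ml_zones = ("medial", "lateral")
    return FitReport(
        max_overhang=max(zones[z]["overhang"] for z in ml_zones),
        max_underhang=max(zones[z]["underhang"] for z in ml_zones),
        zones=zones,
        samples=np.array(records) if keep_samples else None,
    )


def evaluate_cut_fits(mesh, planes, implant, cuts=("distal", "anterior", "posterior")):
    """Bone-vs-implant FitReport per cut plane.

    The distal-cut report is what drives size refinement (mediolateral
    fit); anterior and posterior reports are informational.  Chamfer cuts
    are excluded.
    """
    out = {}
    for cut in cuts:
        plane = planes.plane(cut)
        contour = intersect_mesh_plane(mesh, plane)
        if not contour.loops:
            continue
        bone = flatten_contour(contour)
        impl = Footprint2D(plane=plane, polygons=[implant.footprint_polygon(cut)])
        impl.area = float(impl.polygons[0].area)
        out[cut] = compute_fit(bone, impl)
    if "distal" not in out:
        raise FootprintError("distal cut does not intersect the bone")
    return out


# --------------------------------------------------------------------------
# size refinement


def refine_size(family, initial, fit_evaluator, config):
    """Walk the size ladder until overhang and underhang thresholds hold.

    Overhang beyond ``config.overhang_threshold`` steps one size down;
    otherwise underhang beyond ``config.underhang_threshold`` steps one
    size up.  Each size is visited at most once.  If no size satisfies
    both, the visited size with overhang within threshold and the
    smallest overhang wins (overhang priority — oversized components are
    the worse failure mode), and the result is flagged unsatisfiable.

    Returns ``(final_size, trace)`` where trace rows are
    ``(size, FitReport, action)``.
    """
    sizes = family.sizes
    idx = next(i for i, s in enumerate(sizes) if s.label == initial.label)
    visited: dict[int, FitReport] = {}
    trace = []
    unsatisfiable = False
    while True:
        rep = visited.get(idx)
        if rep is None:
            rep = fit_evaluator(sizes[idx])
            visited[idx] = rep
        if rep.max_overhang > config.overhang_threshold:
            if idx - 1 >= 0 and (idx - 1) not in visited:
                trace.append((sizes[idx].label, rep, "downsize"))
                idx -= 1
                continue
            trace.append((sizes[idx].label, rep, "stop"))
            unsatisfiable = True
            break
        if rep.max_underhang > config.underhang_threshold:
            if idx + 1 < len(sizes) and (idx + 1) not in visited:
                trace.append((sizes[idx].label, rep, "upsize"))
                idx += 1
                continue
            trace.append((sizes[idx].label, rep, "stop"))
            unsatisfiable = True
            break
        trace.append((sizes[idx].label, rep, "accept"))
        break
    if unsatisfiable:
        ok = [i for i, r in visited.items() if r.max_overhang <= config.overhang_threshold]
        pool = ok if ok else list(visited)
        idx = min(pool, key=lambda i: (visited[i].max_overhang,
                                       visited[i].max_underhang,
                                       sizes[i].ap_height))
    final = sizes[idx]
    return final, {"steps": trace, "unsatisfiable": unsatisfiable,
                   "final": final.label, "reports": {sizes[i].label: r for i, r in visited.items()}}


# --------------------------------------------------------------------------
# thickness and notching


def _thickness_at(plane: Plane, point: np.ndarray) -> float:
    # cut-plane normals point into the retained bone; resected material
    # lies on the negative side
    return float(max(0.0, -plane.signed_distance(point)[0]))


def measure_thicknesses(planes, landmarks) -> ResectionThicknesses:
    """Resected thickness at each condylar landmark, along the cut normal.

    A landmark already on the retained side of its cut contributes 0 (no
    bone removed there).
    """
    return ResectionThicknesses(
        FACL=_thickness_at(planes.anterior, landmarks.anterior_lateral),
        FACM=_thickness_at(planes.anterior, landmarks.anterior_medial),
        FPCL=_thickness_at(planes.posterior, landmarks.posterior_lateral),
        FPCM=_thickness_at(planes.posterior, landmarks.posterior_medial),
        FDCL=_thickness_at(planes.distal, landmarks.distal_lateral),
        FDCM=_thickness_at(planes.distal, landmarks.distal_medial),
    )


def detect_notching(mesh: trimesh.Trimesh, anterior_plane: Plane,
                    flange_proximal_extent: float, frame,
                    band: float = 20.0) -> NotchReport:
    """Anterior-cortex notching check proximal to the flange edge.

    Vertices within ``band`` mm proximal of the flange's proximal edge
    (``flange_proximal_extent``, a PD coordinate in ``frame``) are tested
    for penetration anterior to the anterior cut plane; the deepest
    penetration beyond a 0.05 mm numerical gate counts as a notch.
    """
    v = mesh.vertices.view(np.ndarray)
    pd = (v - frame.origin) @ frame.PD
    sel = (pd > flange_proximal_extent) & (pd <= flange_proximal_extent + band)
    if not sel.any():
        return NotchReport(notched=False, notch_depth=0.0)
    anterior_dir = -anterior_plane.normal  # inward normal points posterior
    depth = (v[sel] - anterior_plane.origin) @ anterior_dir
    k = int(np.argmax(depth))
    dmax = float(depth[k])
    if dmax <= NOTCH_GATE:
        return NotchReport(notched=False, notch_depth=0.0)
    return NotchReport(notched=True, notch_depth=dmax, notch_location=v[sel][k])
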