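"""Anatomical frame, alignment axes and angular comparisons.

Axis vocabulary (all directions distal-to-proximal or medial-to-lateral):

* TEA  — transepicondylar axis, through the epicondylar prominences.
* PCA  — posterior condylar axis, through the posterior-most point of each
  condyle; ``PCA+3`` is the PCA externally rotated 3 degrees, the common
  rotational target for the femoral component.
* DAA  — distal anatomic axis, a total-least-squares line through the
  cross-section centroids of the distal third of the shaft; it emulates an
  intramedullary guide rod.
* MA-1 — mechanical axis used in navigation: femoral head centre to knee
  centre (knee centre = TEA intersected with the patellar groove plane).
* MA-2 — head centre to the point where the DAA exits the distal surface.

The anatomical frame is right-handed with ML medial-to-lateral, AP
posterior-to-anterior and PD distal-to-proximal.  Left femurs are handled
by mirroring to the right-handed convention and mirroring results back
(see :mod:`femplan.report`); the functions here assume a right femur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .geometry import (
    Axis3D,
    Plane,
    angle_between_deg,
    fit_line_tls,
    fit_plane_tls,
    intersect_line_plane,
    ray_mesh_intersections,
    rotation_about_axis,
    unit,
)

__all__ = [
    "AnatomicalFrame",
    "AxisSet",
    "AngleReport",
    "CondylarLandmarks",
    "LandmarkError",
    "DegenerateAxisError",
    "DegenerateFitError",
    "anatomical_frame",
    "fit_sphere",
    "compute_head_center",
    "compute_daa",
    "compute_condylar_landmarks",
    "extract_groove_plane",
    "compute_knee_center",
    "build_axis_set",
    "angle_3d",
    "decompose_fe_vv",
    "angle_report",
]


class LandmarkError(RuntimeError):
    """A required landmark could not be located on the mesh."""


class DegenerateAxisError(RuntimeError):
    """Too few usable cross-sections to fit an axis."""


class DegenerateFitError(RuntimeError):
    """Point set insufficient for the requested geometric fit."""


class DecompositionError(RuntimeError):
    """Axis parallel to a projection-plane normal; FE/VV undefined."""


#: extent of the condylar band proximal to the most distal point (mm)
CONDYLAR_BAND = 32.0
#: trochlear-groove search window relative to the posterior condyles (mm)
GROOVE_WINDOW = (-2.0, 14.0)
#: vertices within this distance of the extreme are averaged to de-noise
#: extremal landmarks on tessellated surfaces (mm)
PLATEAU_TOL = 0.5


@dataclass(frozen=True)
class AnatomicalFrame:
    """Right-handed orthonormal anatomical frame (mm, unit vectors)."""

    origin: np.ndarray
    ML: np.ndarray  # medial -> lateral
    AP: np.ndarray  # posterior -> anterior
    PD: np.ndarray  # distal -> proximal

    def project(self, points: np.ndarray) -> np.ndarray:
        """Coordinates of points in the frame, columns (ml, ap, pd)."""
        d = np.atleast_2d(np.asarray(points, float)) - self.origin
        return np.column_stack([d @ self.ML, d @ self.AP, d @ self.PD])


@dataclass
class CondylarLandmarks:
    epicondyle_medial: np.ndarray
    epicondyle_lateral: np.ndarray
    posterior_medial: np.ndarray
    posterior_lateral: np.ndarray
    distal_medial: np.ndarray
    distal_lateral: np.ndarray
    anterior_medial: np.ndarray
    anterior_lateral: np.ndarray
    most_distal: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return dict(self.__dict__)


@dataclass
class AxisSet:
    """All named alignment axes plus their defining points."""

    TEA: Axis3D
    PCA: Axis3D
    DAA: Axis3D
    MA1: Axis3D
    MA2: Axis3D
    PCA_plus3: Axis3D
    knee_center: np.ndarray
    head_center: np.ndarray
    daa_exit_point: np.ndarray
    most_distal_point: np.ndarray
    frame: AnatomicalFrame
    landmarks: CondylarLandmarks
    groove_plane: Plane

    def axis(self, name: str) -> Axis3D:
        key = {"MA1": "MA1", "MA2": "MA2", "DAA": "DAA", "TEA": "TEA",
               "PCA": "PCA", "PCA3": "PCA_plus3", "PCA_PLUS3": "PCA_plus3"}[name.upper()]
        return getattr(self, key)

    def to_dict(self) -> dict:
        def ax(a: Axis3D):
            return {"point": a.point.tolist(), "direction": a.direction.tolist()}

        return {
            "axes": {k: ax(getattr(self, k)) for k in ("TEA", "PCA", "DAA", "MA1", "MA2", "PCA_plus3")},
            "knee_center": self.knee_center.tolist(),
            "head_center": self.head_center.tolist(),
            "daa_exit_point": self.daa_exit_point.tolist(),
            "most_distal_point": self.most_distal_point.tolist(),
            "landmarks": {k: v.tolist() for k, v in self.landmarks.as_dict().items()},
        }


@dataclass
class AngleReport:
    """Angular differences between alignment axes, degrees.

    Magnitude fields are unsigned (0-90); ``signed`` holds the same
    quantities with flexion-positive / valgus-positive signs.
    """

    pca_tea: float
    ma1_daa_fe: float
    ma1_daa_vv: float
    ma1_ma2_fe: float
    ma1_ma2_vv: float
    signed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {k: round(getattr(self, k), 3)
               for k in ("pca_tea", "ma1_daa_fe", "ma1_daa_vv", "ma1_ma2_fe", "ma1_ma2_vv")}
        out["signed"] = {k: round(v, 3) for k, v in self.signed.items()}
        return out


# --------------------------------------------------------------------------
# frame detection


def _extremal_point(vertices: np.ndarray, direction: np.ndarray,
                    tol: float = PLATEAU_TOL, weighted: bool = False) -> np.ndarray:
    """Average of the vertices within ``tol`` of the extreme along a direction.

    Averaging the near-extremal plateau suppresses the tessellation jitter
    of argmax on a faceted surface.  With ``weighted`` the average is
    biased towards the extreme (linear weights over the plateau), which
    localises small prominences such as the epicondyles more tightly.
    """
    proj = vertices @ direction
    m = proj.max()
    sel = proj > m - tol
    if not weighted:
        return vertices[sel].mean(axis=0)
    w = proj[sel] - (m - tol)
    return (vertices[sel] * w[:, None]).sum(axis=0) / w.sum()


def _section_width(vertices: np.ndarray, axis_dir: np.ndarray) -> float:
    d = vertices - vertices.mean(axis=0)
    d = d - np.outer(d @ axis_dir, axis_dir)
    if len(d) < 3:
        return 0.0
    _, s, _ = np.linalg.svd(d, full_matrices=False)
    return float(s[0]) / np.sqrt(len(d))


def anatomical_frame(mesh: trimesh.Trimesh, side: str = "right") -> AnatomicalFrame:
    """Detect a provisional anatomical frame from mesh geometry alone.

    PD is the principal axis of the vertex cloud, oriented so the wider
    (condylar) end is distal.  ML is the principal spread of the distal
    band; AP points away from the posterior condylar mass.  ``side``
    resolves the medial/lateral sign (a left femur should normally be
    mirrored before calling; see module docstring).
    """
    if side not in ("right", "left"):
        raise ValueError("side must be 'right' or 'left'")
    v = mesh.vertices.view(np.ndarray)
    centroid = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - centroid, full_matrices=False)
    pd = unit(vt[0])
    t = (v - centroid) @ pd
    span = t.max() - t.min()
    low = v[t < t.min() + 0.10 * span]
    high = v[t > t.max() - 0.10 * span]
    # the condylar end is much wider than the head/neck end
    if _section_width(low, pd) < _section_width(high, pd):
        pd = -pd
        t = -t
    band = v[t < t.min() + 0.15 * span]
    d = band - band.mean(axis=0)
    d = d - np.outer(d @ pd, pd)
    _, _, vt2 = np.linalg.svd(d, full_matrices=False)
    ml0 = unit(vt2[0] - np.dot(vt2[0], pd) * pd)  # condylar width direction
    ap = unit(np.cross(pd, ml0))
    # AP sign: in the most distal 12 mm the posterior condylar mass puts
    # the slab centroid well posterior of the bone's long axis
    slab = v[t < t.min() + 12.0]
    axis_point = centroid + np.mean((slab - centroid) @ pd) * pd
    if np.dot(slab.mean(axis=0) - axis_point, ap) > 0:
        ap = -ap
    ml = unit(np.cross(ap, pd))  # right-handed: ML x AP = PD
    if side == "left":
        ml = -ml
    return AnatomicalFrame(origin=band.mean(axis=0), ML=ml, AP=ap, PD=pd)


# --------------------------------------------------------------------------
# sphere fitting and head centre


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares sphere fit.

    Returns (center, radius, rms of geometric residuals).  Requires at
    least four non-coplanar points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 4:
        raise DegenerateFitError("need at least 4 points for a sphere fit")
    A = np.column_stack([2.0 * pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateFitError("points are coplanar; sphere fit degenerate")
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise DegenerateFitError("negative squared radius in sphere fit")
    radius = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(pts - center, axis=1) - radius) ** 2)))
    return center, radius, rms


def compute_head_center(mesh: trimesh.Trimesh, frame_hint: AnatomicalFrame,
                        region_fraction: float = 0.15,
                        rms_gate: float = 1.0) -> np.ndarray:
    """Locate the femoral head centre by a trimmed sphere fit.

    Takes vertices in the proximal ``region_fraction`` of the bone length
    and iteratively trims the worst residuals until the densest
    sphere-like subset remains.  The fit is rejected (LandmarkError) when
    no subset passes the RMS / radius / support gates — e.g. when the
    proximal femur is missing from the mesh.
    """
    v = mesh.vertices.view(np.ndarray)
    t = (v - frame_hint.origin) @ frame_hint.PD
    cut = t.max() - region_fraction * (t.max() - t.min())
    region = v[t > cut]
    t_region = t[t > cut]
    if len(region) < 50:
        raise LandmarkError("no proximal head region found")
    # seed on the proximal 25 mm cap (pure head on an intact femur),
    # then grow by residual so neck and shaft never bias the fit
    cap = region[t_region > t_region.max() - 25.0]
    if len(cap) < 20:
        raise LandmarkError("proximal cap too sparse for a sphere fit")
    center, radius, rms = fit_sphere(cap)
    for _ in range(6):
        res = np.abs(np.linalg.norm(region - center, axis=1) - radius)
        sel = res < max(1.0, 2.0 * rms)
        if sel.sum() < 20:
            break
        center, radius, rms = fit_sphere(region[sel])
    res = np.abs(np.linalg.norm(region - center, axis=1) - radius)
    inliers = region[res < max(0.5, 2.0 * rms)]
    # a true head covers its proximal pole; a shaft/neck fit leaves the
    # polar cap of the fitted sphere empty
    dirs = (inliers - center) / max(radius, 1e-9)
    pole_frac = float(np.mean(dirs @ frame_hint.PD > 0.85)) if len(inliers) else 0.0
    if (rms > rms_gate or not (15.0 <= radius <= 45.0)
            or len(inliers) < 0.5 * len(cap) or pole_frac < 0.02):
        raise LandmarkError(
            f"no sphere-like head region (rms={rms:.2f} mm, radius={radius:.1f} mm, "
            f"pole coverage={pole_frac:.1%})")
    return center


# --------------------------------------------------------------------------
# shaft sectioning and the distal anatomic axis


def _section_polygons(mesh, plane: Plane):
    """Shapely polygons of one planar cross-section (may be empty)."""
    from .resection import flatten_contour, intersect_mesh_plane

    contour = intersect_mesh_plane(mesh, plane)
    if not contour.loops:
        return None
    return flatten_contour(contour)


def compute_daa(mesh: trimesh.Trimesh, frame: AnatomicalFrame,
                spacing: float = 2.0) -> Axis3D:
    """Distal anatomic axis: centroid line of the distal third of the shaft.

    The shaft is isolated as the longest contiguous run of cross-sections
    (perpendicular to the provisional long axis) whose area stays below
    twice the median section area — this excludes the condylar flare and
    the femoral head.  Centroids of the distal third of that run are fit
    with a total-least-squares line, oriented distal to proximal.
    """
    v = mesh.vertices.view(np.ndarray)
    centroid = v.mean(axis=0)
    _, _, vt = np.linalg.svd(v - centroid, full_matrices=False)
    long_axis = unit(vt[0]) if np.dot(vt[0], frame.PD) > 0 else -unit(vt[0])
    t = (v - centroid) @ long_axis
    heights = np.arange(t.min() + 2.0, t.max() - 2.0, spacing)
    areas = np.full(len(heights), np.nan)
    cents = np.zeros((len(heights), 3))
    for i, h in enumerate(heights):
        plane = Plane(origin=centroid + h * long_axis, normal=long_axis)
        fp = _section_polygons(mesh, plane)
        if fp is None or fp.area <= 0:
            continue
        areas[i] = fp.area
        c2 = fp.centroid
        cents[i] = plane.to_3d([c2])[0]
    ok = np.isfinite(areas)
    if ok.sum() < 5:
        raise DegenerateAxisError("too few usable shaft cross-sections")
    median_area = np.median(areas[ok])
    # 1.5x the median shaft area cleanly rejects the tail of the condylar
    # flare while keeping neck-region sections
    shaftlike = ok & (areas <= 1.5 * median_area)
    # longest contiguous run of shaft-like sections
    best, cur, start, best_span = None, None, 0, 0
    for i, flag in enumerate(list(shaftlike) + [False]):
        if flag and cur is None:
            cur = i
        elif not flag and cur is not None:
            if i - cur > best_span:
                best, best_span = (cur, i), i - cur
            cur = None
    if best is None or best_span < 5:
        raise DegenerateAxisError("shaft region not found")
    i0, i1 = best
    # the first sections of the run can straddle the flare boundary; drop
    # them until the area settles onto the shaft level
    run_median = np.median(areas[i0:i1][np.isfinite(areas[i0:i1])])
    while i0 < i1 - 5 and areas[i0] > 1.2 * run_median:
        i0 += 1
    best_span = i1 - i0
    third = max(5, int(np.ceil(best_span / 3.0)))
    sel = slice(i0, i0 + third)
    axis = fit_line_tls(cents[sel][np.isfinite(areas[sel])])
    if np.dot(axis.direction, frame.PD) < 0:
        axis = Axis3D(axis.point, -axis.direction)
    return axis


# --------------------------------------------------------------------------
# condylar landmarks, groove plane, knee centre


def compute_condylar_landmarks(mesh: trimesh.Trimesh, frame: AnatomicalFrame) -> CondylarLandmarks:
    """Extremal condylar points in the anatomical frame.

    The two condyles are separated at the median ML coordinate of the
    condylar band (a surrogate for the intercondylar notch plane);
    posterior/distal/anterior extremes and the epicondylar ML extremes are
    plateau-averaged per condyle.
    """
    v = mesh.vertices.view(np.ndarray)
    coords = frame.project(v)
    ml, ap, pd = coords.T
    pd_min = pd.min()
    band_sel = pd < pd_min + CONDYLAR_BAND
    if band_sel.sum() < 100:
        raise LandmarkError("distal condylar band missing or too sparse")
    band = v[band_sel]
    bml = ml[band_sel]
    split = np.median(bml)
    med = band[bml < split]
    lat = band[bml >= split]
    if len(med) < 20 or len(lat) < 20:
        raise LandmarkError("cannot separate the condyles")
    return CondylarLandmarks(
        epicondyle_medial=_extremal_point(med, -frame.ML, tol=1.0, weighted=True),
        epicondyle_lateral=_extremal_point(lat, frame.ML, tol=1.0, weighted=True),
        posterior_medial=_extremal_point(med, -frame.AP),
        posterior_lateral=_extremal_point(lat, -frame.AP),
        distal_medial=_extremal_point(med, -frame.PD),
        distal_lateral=_extremal_point(lat, -frame.PD),
        anterior_medial=_extremal_point(med, frame.AP),
        anterior_lateral=_extremal_point(lat, frame.AP),
        most_distal=_extremal_point(band, -frame.PD),
    )


def extract_groove_plane(mesh: trimesh.Trimesh, frame: AnatomicalFrame,
                         landmarks: CondylarLandmarks,
                         spacing: float = 0.5) -> Plane:
    """Total-least-squares plane through the patellar sulcus polyline.

    For each transverse section across the trochlear span the deepest
    point of the anterior envelope (the sulcus) is located between the
    condylar peaks; the plane through those points approximates the
    patellar groove plane.  Its normal is oriented to point laterally.
    """
    post_pd = 0.5 * (
        frame.project(landmarks.posterior_medial)[0, 2]
        + frame.project(landmarks.posterior_lateral)[0, 2]
    )
    ml_lo = frame.project(landmarks.anterior_medial)[0, 0] + 4.0
    ml_hi = frame.project(landmarks.anterior_lateral)[0, 0] - 4.0
    base = frame.origin + (post_pd + GROOVE_WINDOW[0]) * frame.PD
    n_sections = int((GROOVE_WINDOW[1] - GROOVE_WINDOW[0]) / spacing) + 1
    sulcus = []
    for i in range(n_sections):
        plane = Plane(origin=base + i * spacing * frame.PD, normal=frame.PD,
                      u=frame.ML, v=frame.AP)
        fp = _section_polygons(mesh, plane)
        if fp is None:
            continue
        pts2 = np.vstack([np.asarray(p.exterior.coords) for p in fp.polygons])
        sel = (pts2[:, 0] > ml_lo) & (pts2[:, 0] < ml_hi) & (pts2[:, 1] > np.median(pts2[:, 1]))
        pts2 = pts2[sel]
        if len(pts2) < 10:
            continue
        # anterior envelope in 1 mm ML bins
        bins = np.floor(pts2[:, 0] - ml_lo).astype(int)
        nb = bins.max() + 1
        env = np.full(nb, -np.inf)
        np.maximum.at(env, bins, pts2[:, 1])
        valid = np.isfinite(env)
        if valid.sum() < 5:
            continue
        idx = np.flatnonzero(valid)
        k = idx[1:-1][np.argmin(env[idx[1:-1]])] if len(idx) > 2 else None
        if k is None:
            continue
        left_max = env[idx[idx < k]].max()
        right_max = env[idx[idx > k]].max()
        if env[k] > min(left_max, right_max) - 1.0:
            continue  # no real concavity in this section
        near = pts2[np.abs(bins - k) <= 2]
        # sub-bin sulcus: the groove cross-section is a shallow arc, so a
        # parabola through the near-minimum points localises the deepest
        # point far better than the rawest contour vertex
        deepest = near[np.argmin(near[:, 1])]
        fitpts = near[near[:, 1] < deepest[1] + 3.0]
        if len(fitpts) >= 5:
            a, b, c = np.polyfit(fitpts[:, 0], fitpts[:, 1], 2)
            if a > 1e-6:
                xv = float(np.clip(-b / (2 * a), near[:, 0].min(), near[:, 0].max()))
                deepest = np.array([xv, a * xv * xv + b * xv + c])
        sulcus.append(plane.to_3d([deepest])[0])
    if len(sulcus) < 5:
        raise LandmarkError("trochlear sulcus not found")
    pts = np.array(sulcus)
    plane = fit_plane_tls(pts)
    # one robust re-fit: a section that caught a spurious dip would
    # otherwise dominate the nearly-collinear sulcus polyline
    res = np.abs(plane.signed_distance(pts))
    keep = res <= max(3.0 * np.median(res), 0.3)
    if keep.sum() >= 5 and keep.sum() < len(pts):
        plane = fit_plane_tls(pts[keep])
    if np.dot(plane.normal, frame.ML) < 0:
        plane = Plane(origin=plane.origin, normal=-plane.normal, u=plane.u)
    return plane


def compute_knee_center(TEA: Axis3D, groove_plane: Plane) -> np.ndarray:
    """Knee centre: intersection of the TEA with the patellar groove plane."""
    try:
        return intersect_line_plane(TEA, groove_plane, parallel_tol=1e-6)
    except ValueError as exc:
        raise LandmarkError(f"TEA parallel to groove plane: {exc}") from exc


# --------------------------------------------------------------------------
# the axis set


def _external_sign(pca_dir: np.ndarray, tea_dir: np.ndarray, pd: np.ndarray) -> float:
    """Sign of the rotation that carries the PCA towards the TEA about PD."""
    s = float(np.dot(np.cross(pca_dir, tea_dir), pd))
    return 1.0 if s >= 0 else -1.0


def build_axis_set(mesh: trimesh.Trimesh, frame: AnatomicalFrame | None = None,
                   side: str = "right") -> AxisSet:
    """Compute every alignment axis and the refined anatomical frame.

    PCA+3 is the PCA rotated exactly 3 degrees about the axis
    perpendicular to it in the PCA-PD plane (so the 3 degree construction
    invariant holds to machine precision), in the external direction —
    i.e. towards the TEA.
    """
    frame = frame or anatomical_frame(mesh, side=side)
    head = compute_head_center(mesh, frame)
    daa = compute_daa(mesh, frame)

    def landmarks_and_knee(fr):
        lm = compute_condylar_landmarks(mesh, fr)
        tea = Axis3D(point=lm.epicondyle_medial,
                     direction=lm.epicondyle_lateral - lm.epicondyle_medial)
        pca = Axis3D(point=lm.posterior_medial,
                     direction=lm.posterior_lateral - lm.posterior_medial)
        groove = extract_groove_plane(mesh, fr, lm)
        knee = compute_knee_center(tea, groove)
        return lm, tea, pca, groove, knee

    def mech_frame(knee, tea_dir, fr):
        # PD along MA-1, ML along the TEA, origin at the knee centre
        pd = unit(head - knee)
        if np.dot(pd, fr.PD) < 0:
            pd = -pd
        ml = unit(tea_dir - np.dot(tea_dir, pd) * pd)
        if np.dot(ml, fr.ML) < 0:
            ml = -ml
        ap = np.cross(pd, ml)
        return AnatomicalFrame(origin=knee, ML=ml, AP=ap, PD=pd)

    # landmarks found in the provisional frame define a mechanical-axis
    # frame; extremal landmarks are then re-taken in that frame so the
    # result does not depend on the provisional long-axis tilt
    lm, tea, pca, groove, knee = landmarks_and_knee(frame)
    refined = mech_frame(knee, tea.direction, frame)
    lm, tea, pca, groove, knee = landmarks_and_knee(refined)
    refined = mech_frame(knee, tea.direction, refined)
    ma1 = Axis3D(point=knee, direction=head - knee)

    # DAA exit: first crossing of the distal surface walking distally
    hits = ray_mesh_intersections(mesh, daa.point, -daa.direction)
    if len(hits) == 0:
        raise LandmarkError("DAA does not exit through the distal surface")
    exit_point = hits[-1]  # farthest hit along the distal ray = distal surface
    ma2 = Axis3D(point=exit_point, direction=head - exit_point)

    rot_axis = unit(refined.PD - np.dot(refined.PD, pca.direction) * pca.direction)
    sign = _external_sign(pca.direction, tea.direction, refined.PD)
    pca3_dir = rotation_about_axis(rot_axis, 3.0 * sign) @ pca.direction
    pca3 = Axis3D(point=pca.point, direction=pca3_dir)

    return AxisSet(
        TEA=tea, PCA=pca, DAA=daa, MA1=ma1, MA2=ma2, PCA_plus3=pca3,
        knee_center=knee, head_center=head, daa_exit_point=exit_point,
        most_distal_point=lm.most_distal, frame=refined, landmarks=lm,
        groove_plane=groove,
    )


# --------------------------------------------------------------------------
# angles


def angle_3d(a: Axis3D | np.ndarray, b: Axis3D | np.ndarray) -> float:
    """Orientation-free 3D angle between two axes, degrees in [0, 90]."""
    da = a.direction if isinstance(a, Axis3D) else np.asarray(a, float)
    db = b.direction if isinstance(b, Axis3D) else np.asarray(b, float)
    return angle_between_deg(da, db, orientation_free=True)


def _project_signed(a, b, normal, sign_ref) -> float:
    an = a - np.dot(a, normal) * normal
    bn = b - np.dot(b, normal) * normal
    if np.linalg.norm(an) < 1e-9 or np.linalg.norm(bn) < 1e-9:
        raise DecompositionError("axis parallel to projection-plane normal")
    an, bn = unit(an), unit(bn)
    ang = np.degrees(np.arctan2(np.dot(np.cross(an, bn), sign_ref),
                                np.clip(np.dot(an, bn), -1, 1)))
    return float(ang)


def decompose_fe_vv(a: Axis3D, b: Axis3D, frame: AnatomicalFrame) -> tuple[float, float]:
    """Flexion/extension and varus/valgus components of the angle a -> b.

    FE is measured between the sagittal-plane projections (plane normal
    ML), positive when ``b`` is more flexed than ``a``; VV between the
    coronal-plane projections (normal AP), positive when ``b`` is more
    valgus (its proximal end more lateral).
    """
    da = a.direction if np.dot(a.direction, frame.PD) >= 0 else -a.direction
    db = b.direction if np.dot(b.direction, frame.PD) >= 0 else -b.direction
    fe = _project_signed(da, db, frame.ML, frame.ML)
    vv = _project_signed(da, db, frame.AP, frame.AP)
    return fe, vv


def angle_report(axes: AxisSet) -> AngleReport:
    """The five inter-axis angular differences."""
    fe_daa, vv_daa = decompose_fe_vv(axes.MA1, axes.DAA, axes.frame)
    fe_ma2, vv_ma2 = decompose_fe_vv(axes.MA1, axes.MA2, axes.frame)
    signed = {
        "ma1_daa_fe": fe_daa, "ma1_daa_vv": vv_daa,
        "ma1_ma2_fe": fe_ma2, "ma1_ma2_vv": vv_ma2,
    }
    return AngleReport(
        pca_tea=angle_3d(axes.PCA, axes.TEA),
        ma1_daa_fe=abs(fe_daa), ma1_daa_vv=abs(vv_daa),
        ma1_ma2_fe=abs(fe_ma2), ma1_ma2_vv=abs(vv_ma2),
        signed=signed,
    )
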