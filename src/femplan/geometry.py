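"""Low-level 3D primitives shared across the planning pipeline.

Everything works in millimetres on plain numpy arrays.  A :class:`Plane`
carries an explicit in-plane basis ``(u, v)`` so that 2D footprint
coordinates are well defined and comparable between the bone contour and
the implant polygon living on the same cut plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Plane",
    "Axis3D",
    "unit",
    "rotation_about_axis",
    "fit_line_tls",
    "fit_plane_tls",
    "intersect_line_plane",
    "ray_mesh_intersections",
    "angle_between_deg",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a vector; raises on zero length."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize zero-length vector")
    return v / n


def _any_perpendicular(n: np.ndarray) -> np.ndarray:
    # pick the coordinate axis least aligned with n for a stable basis
    a = np.eye(3)[np.argmin(np.abs(n))]
    return unit(np.cross(n, a))


@dataclass(frozen=True)
class Axis3D:
    """An infinite oriented line: a point on it and a unit direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction", unit(self.direction))

    def at(self, t: float) -> np.ndarray:
        return self.point + t * self.direction


@dataclass(frozen=True)
class Plane:
    """A plane with unit normal and an orthonormal in-plane basis.

    2D plane coordinates of a 3D point ``p`` are
    ``((p - origin)·u, (p - origin)·v)``.
    """

    origin: np.ndarray
    normal: np.ndarray
    u: np.ndarray = field(default=None)  # type: ignore[assignment]
    v: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        n = unit(self.normal)
        object.__setattr__(self, "normal", n)
        u = self.u
        if u is None:
            u = _any_perpendicular(n)
        else:
            u = unit(np.asarray(u, float) - np.dot(u, n) * n)
        v = self.v
        if v is None:
            v = np.cross(n, u)
        else:
            v = unit(np.asarray(v, float))
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.origin) @ self.normal

    def to_2d(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = points - self.origin
        return np.column_stack([d @ self.u, d @ self.v])

    def to_3d(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return self.origin + np.outer(coords[:, 0], self.u) + np.outer(coords[:, 1], self.v)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(unit(axis) * np.deg2rad(angle_deg)).as_matrix()


def fit_line_tls(points: np.ndarray) -> Axis3D:
    """Total-least-squares 3D line through a point cloud (first PC)."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points for a line fit")
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return Axis3D(point=c, direction=vt[0])


def fit_plane_tls(points: np.ndarray) -> Plane:
    """Total-least-squares plane (normal = last principal direction).

    Raises if the points are (numerically) collinear, in which case the
    plane is not identifiable.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise ValueError("need at least 3 points for a plane fit")
    c = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - c, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; plane fit is degenerate")
    return Plane(origin=c, normal=vt[2], u=vt[0])


def intersect_line_plane(axis: Axis3D, plane: Plane, parallel_tol: float = 1e-9) -> np.ndarray:
    denom = float(np.dot(axis.direction, plane.normal))
    if abs(denom) < parallel_tol:
        raise ValueError("line is parallel to plane; no unique intersection")
    t = -float(np.dot(axis.point - plane.origin, plane.normal)) / denom
    return axis.at(t)


def ray_mesh_intersections(mesh, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """All intersection points of a single ray with a triangle mesh.

    Vectorized Moller-Trumbore over every face; returns hits sorted by ray
    parameter t >= 0, shape (k, 3).  Brute force, but a femur mesh has only
    a few hundred thousand faces and the planner casts a handful of rays.
    """
    origin = np.asarray(origin, dtype=float)
    d = unit(direction)
    tri = mesh.triangles  # (n, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(d, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    tvec = origin - v0
    uu = np.einsum("ij,ij->i", tvec, pvec) * inv
    qvec = np.cross(tvec, e1)
    vv = np.dot(qvec, d) * inv
    t = np.einsum("ij,ij->i", e2, qvec) * inv
    hit = ok & (uu >= -1e-9) & (vv >= -1e-9) & (uu + vv <= 1 + 1e-9) & (t > 1e-9)
    th = np.sort(t[hit])
    # a ray through a shared edge/vertex hits several triangles at one t
    if len(th):
        th = th[np.concatenate([[True], np.diff(th) > 1e-6])]
    return origin + np.outer(th, d)


def angle_between_deg(a: np.ndarray, b: np.ndarray, orientation_free: bool = True) -> float:
    """Angle between two directions in degrees.

    With ``orientation_free`` the sign of either vector is ignored and the
    result lies in [0, 90]; otherwise in [0, 180].
    """
    ca = float(np.dot(unit(a), unit(b)))
    if orientation_free:
        ca = abs(ca)
    return float(np.degrees(np.arccos(np.clip(ca, -1.0, 1.0))))


def point_triangle_distances(point: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Distance from one point to each triangle (vectorized exact test)."""
    p = np.asarray(point, dtype=float)
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    nearest = np.empty_like(triangles[:, 0])
    # vertex regions
    nearest[:] = a
    mask_b = (d3 >= 0) & (d4 <= d3)
    nearest[mask_b] = b[mask_b]
    mask_c = (d6 >= 0) & (d5 <= d6)
    nearest[mask_c] = c[mask_c]
    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    w = np.where(np.abs(d1 - d3) > 1e-30, d1 / (d1 - d3), 0.0)
    nearest[m] = a[m] + w[m, None] * ab[m]
    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.where(np.abs(d2 - d6) > 1e-30, d2 / (d2 - d6), 0.0)
    nearest[m] = a[m] + w[m, None] * ac[m]
    # edge BC
    va = d3 * d6 - d5 * d4
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(np.abs(denom) > 1e-30, (d4 - d3) / denom, 0.0)
    nearest[m] = b[m] + w[m, None] * (c[m] - b[m])
    # interior
    m = (vc > 0) & (vb > 0) & (va > 0)
    denom = va + vb + vc
    v = vb / np.where(denom == 0, 1.0, denom)
    w = vc / np.where(denom == 0, 1.0, denom)
    nearest[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return np.linalg.norm(nearest - p, axis=1)


def distance_to_surface(mesh, points: np.ndarray) -> np.ndarray:
    """Exact unsigned distance from each point to the mesh surface."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    out = np.empty(len(points))
    for i, p in enumerate(points):
        # prefilter by triangle-centroid distance to keep it fast
        cent = tri.mean(axis=1)
        d2 = np.linalg.norm(cent - p, axis=1)
        keep = tri[d2 < d2.min() + 5.0]
        out[i] = point_triangle_distances(p, keep).min()
    return out
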