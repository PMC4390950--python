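"""Parametric femur-like surface generator with known ground truth.

The bone is assembled as an implicit solid — head sphere, neck capsule,
bowed shaft tube, metaphyseal cone, two condylar spheres, epicondylar and
anterior-condylar prominences, an anterior flange slab and a lateral
anterior ridge — then polygonised with marching cubes, which yields a
watertight triangle mesh by construction.  A trochlear groove is carved
from the flange so a patellar-sulcus polyline exists.

Every landmark the planning pipeline later has to find (head centre,
distal-third shaft axis, condylar extremes, epicondyles, sulcus plane,
ridge saddle) has a closed-form location recorded in :class:`GroundTruth`.
The lateral ridge's anteroposterior profile is a smoothstep with exactly
one inflection, so the "sizing point" (convex-to-concave saddle) is known
exactly; the profile drops below the anterior shaft cortex proximally, so
an anterior cut referenced at the lowest ridge point notches, as it does
on real femurs.

Default dimensions describe an adult femur in millimetres (bone length
~450 mm, head radius 24 mm, bicondylar width ~81 mm, 5.44 deg of
epicondylar twist relative to the posterior condyles).  A cohort is drawn
by jittering those defaults within anatomically plausible ranges
(:func:`sample_params`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from skimage import measure

from .geometry import Axis3D, Plane, fit_line_tls, rotation_about_axis, unit

__all__ = [
    "FemurParams",
    "GroundTruth",
    "generate_femur",
    "perturb_mesh",
    "sample_params",
]


class ParameterError(ValueError):
    """Geometrically impossible or invalid generator parameters."""


@dataclass
class FemurParams:
    """Dimensions of the synthetic femur (mm, degrees).

    ``head_center`` may be left ``None``, in which case it is derived from
    ``neck_angle`` (angle between neck and shaft, ~127 deg in adults) and
    ``neck_length``.
    """

    side: str = "right"
    head_center: tuple | None = None
    head_radius: float = 24.0
    neck_angle: float = 127.0
    neck_length: float = 38.0
    neck_radius: float = 11.5
    shaft_length: float = 360.0
    shaft_radius: float = 14.0
    shaft_bow: float = 4.0          # lateral offset of shaft midline at mid-shaft
    shaft_bow_ap: float = 5.0       # anterior bow at mid-shaft
    condyle_radius_medial: float = 21.0
    condyle_radius_lateral: float = 20.0
    condyle_separation: float = 40.0
    condyle_center_y: float = -12.0
    condyle_center_z: float = 12.0
    condyle_z_drop_medial: float = 4.0   # medial condyle sits more distal
    epicondylar_twist_deg: float = 5.44  # TEA external rotation w.r.t. PCA
    epicondyle_y: float = -12.0
    groove_depth: float = 6.0
    groove_x: float = 3.0
    ridge_saddle_height: float = 18.0    # AP prominence of the saddle
    ridge_drop: float = 5.5              # AP drop from ridge high to ridge low
    ridge_high_low_span: float = 14.0    # PD distance between high and low
    voxel_pitch: float = 1.2
    rng_seed: int = 0

    # fixed anatomical offsets of the construction (mm above distal origin)
    shaft_z0: float = 40.0
    flange_z0: float = 5.0
    flange_z1: float = 50.0
    ridge_z0: float = 28.0

    def validate(self) -> None:
        positive = [
            self.head_radius, self.neck_length, self.neck_radius,
            self.shaft_length, self.shaft_radius,
            self.condyle_radius_medial, self.condyle_radius_lateral,
            self.condyle_separation, self.groove_depth,
            self.ridge_saddle_height, self.ridge_drop,
            self.ridge_high_low_span, self.voxel_pitch,
        ]
        if any(v <= 0 for v in positive):
            raise ParameterError("all lengths must be positive")
        if self.side not in ("right", "left"):
            raise ParameterError("side must be 'right' or 'left'")
        rmax = max(self.condyle_radius_medial, self.condyle_radius_lateral)
        if self.shaft_length <= 4.0 * rmax:
            raise ParameterError("shaft_length must exceed 4x condyle radius")
        if self.condyle_separation <= rmax * 0.5:
            raise ParameterError("condyles overlap: separation too small")
        if self.ridge_drop >= 2.0 * self.ridge_saddle_height:
            raise ParameterError("ridge profile would dip below the cortex plane")
        if self.voxel_pitch > 2.0:
            raise ParameterError(
                "voxel_pitch above 2 mm cannot resolve the trochlear groove "
                "and ridge crest; the surface would not stay manifold")


@dataclass
class GroundTruth:
    """Closed-form landmarks of a generated femur (bone coordinates, mm).

    Axes point distal-to-proximal; the groove plane normal points lateral.
    """

    head_center: np.ndarray
    head_radius: float
    shaft_axis: Axis3D                  # TLS line of the distal-third shaft midline
    epicondyle_medial: np.ndarray
    epicondyle_lateral: np.ndarray
    posterior_medial: np.ndarray
    posterior_lateral: np.ndarray
    distal_medial: np.ndarray
    distal_lateral: np.ndarray
    anterior_medial: np.ndarray
    anterior_lateral: np.ndarray
    most_distal: np.ndarray
    saddle: np.ndarray
    ridge_high: np.ndarray
    ridge_low: np.ndarray
    groove_plane: Plane
    knee_center: np.ndarray
    tea: Axis3D
    pca: Axis3D
    side: str = "right"

    def points(self) -> dict[str, np.ndarray]:
        return {
            k: getattr(self, k)
            for k in (
                "head_center", "epicondyle_medial", "epicondyle_lateral",
                "posterior_medial", "posterior_lateral", "distal_medial",
                "distal_lateral", "anterior_medial", "anterior_lateral",
                "most_distal", "saddle", "ridge_high", "ridge_low",
                "knee_center",
            )
        }


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


class _Construction:
    """Analytic description shared by the field evaluation and the truth."""

    def __init__(self, p: FemurParams):
        self.p = p
        self.z_shaft0 = p.shaft_z0
        self.z_shaft1 = p.shaft_z0 + p.shaft_length
        # neck base sits slightly below the proximal shaft end
        self.neck_base_z = self.z_shaft1 - 15.0
        a = np.deg2rad(180.0 - p.neck_angle)  # angle to the proximal direction
        neck_dir = unit(np.array([-np.sin(a), 0.12, np.cos(a)]))
        base = np.array([*self.shaft_center(self.neck_base_z), self.neck_base_z])
        self.neck_base = base
        if p.head_center is None:
            self.head_center = base + p.neck_length * neck_dir
        else:
            self.head_center = np.asarray(p.head_center, dtype=float)
        # ridge AP profile: smoothstep drop with its inflection at mid-span;
        # proximal of the drop the cortex rises again by ``tubercle_rise``
        # (the ridge's continuation onto the shaft), which is what an
        # anterior cut referenced too low will notch
        self.ridge_z1 = p.ridge_z0 + p.ridge_high_low_span      # end of the drop
        self.h_high = p.ridge_saddle_height + p.ridge_drop / 2.0
        self.h_low = p.ridge_saddle_height - p.ridge_drop / 2.0
        self.tubercle_rise = 2.5
        self.rise_z0 = p.ridge_z0 + 17.0    # proximal tubercle rise, above the search span
        self.ridge_z_end = p.ridge_z0 + 21.5
        self.ridge_x = (8.0, 22.0)
        self.ridge_crown = 0.08    # ML crowning of the crest (mm^-1)
        self.flange_halfwidth = p.condyle_separation / 2.0 + 6.0
        self.flange_back = -14.0
        self.cone_top_z = 42.0
        cy, cz, sep = p.condyle_center_y, p.condyle_center_z, p.condyle_separation
        self.cond_med_c = np.array([-sep / 2, cy, cz - p.condyle_z_drop_medial])
        self.cond_lat_c = np.array([sep / 2, cy, cz])
        # posterior condylar extremes (on the condyle spheres, nominal frame)
        self.post_med = self.cond_med_c + np.array([0.0, -p.condyle_radius_medial, 0.0])
        self.post_lat = self.cond_lat_c + np.array([0.0, -p.condyle_radius_lateral, 0.0])
        pca_dir = unit(self.post_lat - self.post_med)
        tea_dir = rotation_about_axis([0, 0, 1.0], p.epicondylar_twist_deg) @ pca_dir
        self.tea_dir = tea_dir
        anchor = np.array([0.0, p.epicondyle_y, cz - 2.0])
        self.epi_r = 7.0
        # place the epicondylar *extremes* exactly on the rotated TEA line
        xe_m = -(sep / 2 + p.condyle_radius_medial + 4.0)
        xe_l = sep / 2 + p.condyle_radius_lateral + 4.0
        self.epi_med = anchor + tea_dir * ((xe_m - anchor[0]) / tea_dir[0])
        self.epi_lat = anchor + tea_dir * ((xe_l - anchor[0]) / tea_dir[0])
        self.epi_med_c = self.epi_med + np.array([self.epi_r, 0.0, 0.0])
        self.epi_lat_c = self.epi_lat - np.array([self.epi_r, 0.0, 0.0])
        self.ant_bump_r = 6.5
        # anterior condylar prominences: more prominent laterally
        # (FACL > FACM) and proximal of the distal condyles, as on the
        # anterior trochlear margin of a real femur
        self.ant_med_c = np.array([-sep / 2 + 6.0, 21.0, 16.0])
        self.ant_lat_c = np.array([sep / 2 - 6.0, 22.5, 16.0])

    # --- analytic curves ------------------------------------------------
    def shaft_center(self, z):
        z = np.asarray(z, dtype=float)
        mid = 0.5 * (self.z_shaft0 + self.z_shaft1)
        half = 0.5 * (self.z_shaft1 - self.z_shaft0)
        b = np.clip(1.0 - ((z - mid) / half) ** 2, 0.0, None)
        return self.p.shaft_bow * b, self.p.shaft_bow_ap * b

    def flange_face(self, z):
        t = np.asarray(z, dtype=float) - self.p.flange_z0
        return 24.0 - 0.42 * t - 0.002 * t * t

    def ridge_h(self, z):
        z = np.asarray(z, dtype=float)
        t = (z - self.p.ridge_z0) / self.p.ridge_high_low_span
        h = self.h_high - self.p.ridge_drop * _smoothstep(t)
        # proximal re-rise onto the shaft (anterior tubercle)
        tr = (z - self.rise_z0) / 3.0
        return h + self.tubercle_rise * _smoothstep(tr)

    def groove_span(self):
        cz = self.p.condyle_center_z
        return cz - 6.0, cz + 17.0

    def groove_sulcus_y(self, z):
        z = np.asarray(z, dtype=float)
        z0, z1 = self.groove_span()
        # the groove deepens away from mid-trochlea, as the sulcus arcs
        # anteriorly; this also makes the sulcus polyline clearly
        # non-collinear, as on a real trochlea
        depth = self.p.groove_depth + 0.03 * (z - 0.5 * (z0 + z1)) ** 2
        return self.flange_face(z) - depth

    # --- scalar field ---------------------------------------------------
    def field(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Approximate signed distance, negative inside the bone."""
        p = self.p
        x = np.asarray(x, np.float32)
        y = np.asarray(y, np.float32)
        z = np.asarray(z, np.float32)
        d = np.full(x.shape, np.float32(1e9))

        def sphere(c, r):
            return np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2) - r

        def capsule(a, b, r0, r1):
            ab = np.asarray(b, float) - np.asarray(a, float)
            t = ((x - a[0]) * ab[0] + (y - a[1]) * ab[1] + (z - a[2]) * ab[2]) / (ab @ ab)
            t = np.clip(t, 0.0, 1.0)
            dx = x - (a[0] + t * ab[0])
            dy = y - (a[1] + t * ab[1])
            dz = z - (a[2] + t * ab[2])
            return np.sqrt(dx * dx + dy * dy + dz * dz) - (r0 + t * (r1 - r0))

        d = np.minimum(d, sphere(self.head_center, p.head_radius))
        d = np.minimum(d, capsule(self.neck_base, self.head_center, p.neck_radius, p.neck_radius))
        # bowed shaft: radial distance to the midline at the clamped height
        zc = np.clip(z, self.z_shaft0, self.z_shaft1)
        bx, by = self.shaft_center(zc)
        radial = np.sqrt((x - bx) ** 2 + (y - by) ** 2) - p.shaft_radius
        d = np.minimum(d, np.maximum.reduce([radial, self.z_shaft0 - z, z - self.z_shaft1]))
        # metaphyseal cone from the condylar mass up to the shaft; kept
        # slim so its anterior face stays posterior of the lateral ridge
        bx1, by1 = self.shaft_center(self.cone_top_z)
        d = np.minimum(d, capsule((0.0, -1.0, 14.0), (float(bx1), float(by1), self.cone_top_z), 19.0, p.shaft_radius))
        d = np.minimum(d, sphere(self.cond_med_c, p.condyle_radius_medial))
        d = np.minimum(d, sphere(self.cond_lat_c, p.condyle_radius_lateral))
        d = np.minimum(d, sphere(self.epi_med_c, self.epi_r))
        d = np.minimum(d, sphere(self.epi_lat_c, self.epi_r))
        d = np.minimum(d, sphere(self.ant_med_c, self.ant_bump_r))
        d = np.minimum(d, sphere(self.ant_lat_c, self.ant_bump_r))
        # anterior flange slab with curved front face
        w = self.flange_halfwidth
        slab = np.maximum.reduce([
            np.abs(x) - w,
            self.flange_back - y,
            y - self.flange_face(z),
            p.flange_z0 - z,
            z - p.flange_z1,
        ])
        d = np.minimum(d, slab)
        # lateral anterior ridge with crowned front face (unique ML apex)
        x0, x1 = self.ridge_x
        xm = 0.5 * (x0 + x1)
        front = self.ridge_h(z) - self.ridge_crown * (x - xm) ** 2
        # the slab extends 4 mm distal of the profile start (flat at
        # h_high there) so it merges into the lateral trochlear facet
        ridge = np.maximum.reduce([
            x0 - x, x - x1, -y, y - front, (p.ridge_z0 - 4.0) - z, z - self.ridge_z_end,
        ])
        d = np.minimum(d, ridge)
        # carve the trochlear groove (capped tube along the sulcus)
        z0, z1 = self.groove_span()
        zg = np.clip(z, z0, z1)
        r_g = 8.0
        yc = self.groove_sulcus_y(zg) + r_g
        tube = np.maximum.reduce([
            np.sqrt((x - p.groove_x) ** 2 + (y - yc) ** 2) - r_g,
            z0 - z, z - z1,
        ])
        return np.maximum(d, -tube)

    # --- ground truth ---------------------------------------------------
    def _ridge_point_at_pd(self, pd_target: float, knee: np.ndarray,
                           PD: np.ndarray, AP: np.ndarray) -> np.ndarray:
        """Ridge apex point whose PD coordinate equals ``pd_target``.

        The apex of the crowned ridge face shifts off the slab midline
        when the frame AP is tilted; both the apex and the station height
        are solved by fixed-point iteration (the profile is shallow).
        """
        xm = 0.5 * (self.ridge_x[0] + self.ridge_x[1])
        x_apex = xm + AP[0] / (2.0 * self.ridge_crown * AP[1])
        x_apex = float(np.clip(x_apex, self.ridge_x[0], self.ridge_x[1]))
        crown_drop = self.ridge_crown * (x_apex - xm) ** 2
        z = self.p.condyle_center_z + pd_target  # initial guess
        for _ in range(6):
            y = float(self.ridge_h(z)) - crown_drop
            z = (pd_target + PD @ knee - PD[0] * x_apex - PD[1] * y) / PD[2]
        z = float(np.clip(z, self.p.ridge_z0 - 3.0, self.rise_z0 - 0.5))
        return np.array([x_apex, float(self.ridge_h(z)) - crown_drop, z])

    def ground_truth(self) -> GroundTruth:
        from .cortex import RIDGE_WINDOW

        p = self.p
        zs = np.linspace(self.z_shaft0, self.z_shaft0 + p.shaft_length / 3.0, 200)
        bx, by = self.shaft_center(zs)
        axis = fit_line_tls(np.column_stack([bx, by, zs]))
        if axis.direction[2] < 0:
            axis = Axis3D(axis.point, -axis.direction)

        r_m, r_l = p.condyle_radius_medial, p.condyle_radius_lateral
        head = self.head_center

        def support(center, radius, direction):
            return np.asarray(center, float) + radius * unit(direction)

        # landmarks are extremes along the *mechanical* frame directions,
        # which themselves depend on the landmarks -> fixed-point iteration
        tea_dir = self.tea_dir
        knee = np.array([p.groove_x, p.epicondyle_y, p.condyle_center_z])
        groove_x = float(p.groove_x)
        for _ in range(6):
            PD = unit(head - knee)
            ML = unit(tea_dir - np.dot(tea_dir, PD) * PD)
            AP = np.cross(PD, ML)
            epi_med = support(self.epi_med_c, self.epi_r, -ML)
            epi_lat = support(self.epi_lat_c, self.epi_r, ML)
            tea_dir = unit(epi_lat - epi_med)
            # sulcus probing finds the deepest point along the tilted AP,
            # which sits slightly off the carve midline
            groove_x = p.groove_x - 8.0 * AP[0] / float(np.hypot(AP[0], AP[1]))
            tea_line = Axis3D(point=epi_med, direction=tea_dir)
            t = (groove_x - epi_med[0]) / tea_dir[0]
            knee = epi_med + t * tea_dir

        post_med = support(self.cond_med_c, r_m, -AP)
        post_lat = support(self.cond_lat_c, r_l, -AP)
        dist_med = support(self.cond_med_c, r_m, -PD)
        dist_lat = support(self.cond_lat_c, r_l, -PD)
        most_distal = dist_med if (-PD) @ dist_med >= (-PD) @ dist_lat else dist_lat
        ant_med = support(self.ant_med_c, self.ant_bump_r, AP)
        ant_lat = support(self.ant_lat_c, self.ant_bump_r, AP)

        pd_pc = 0.5 * float(PD @ (post_med - knee) + PD @ (post_lat - knee))
        z_saddle = p.ridge_z0 + p.ridge_high_low_span / 2.0
        xm = 0.5 * (self.ridge_x[0] + self.ridge_x[1])
        x_apex = float(np.clip(xm + AP[0] / (2 * self.ridge_crown * AP[1]),
                               self.ridge_x[0], self.ridge_x[1]))
        crown_drop = self.ridge_crown * (x_apex - xm) ** 2
        saddle = np.array([x_apex, float(self.ridge_h(z_saddle)) - crown_drop, z_saddle])
        ridge_high = self._ridge_point_at_pd(pd_pc + RIDGE_WINDOW[0], knee, PD, AP)
        ridge_low = self._ridge_point_at_pd(pd_pc + RIDGE_WINDOW[1], knee, PD, AP)

        groove_plane = Plane(origin=np.array([groove_x, 0.0, 0.0]),
                             normal=np.array([1.0, 0.0, 0.0]),
                             u=np.array([0.0, 1.0, 0.0]))
        return GroundTruth(
            head_center=head.copy(),
            head_radius=p.head_radius,
            shaft_axis=axis,
            epicondyle_medial=epi_med,
            epicondyle_lateral=epi_lat,
            posterior_medial=post_med,
            posterior_lateral=post_lat,
            distal_medial=dist_med,
            distal_lateral=dist_lat,
            anterior_medial=ant_med,
            anterior_lateral=ant_lat,
            most_distal=most_distal,
            saddle=saddle,
            ridge_high=ridge_high,
            ridge_low=ridge_low,
            groove_plane=groove_plane,
            knee_center=knee,
            tea=tea_line,
            pca=Axis3D(point=post_med, direction=unit(post_lat - post_med)),
            side="right",
        )


def _mirror_point(pt: np.ndarray) -> np.ndarray:
    return np.asarray(pt, float) * np.array([-1.0, 1.0, 1.0])


def _mirror_truth(gt: GroundTruth) -> GroundTruth:
    def mir_axis(a: Axis3D) -> Axis3D:
        return Axis3D(_mirror_point(a.point), _mirror_point(a.direction))

    # mirroring across the sagittal plane preserves medial/lateral labels
    # (medial stays towards the midline)
    kwargs = {name: _mirror_point(getattr(gt, name)) for name in gt.points()}
    gp = gt.groove_plane
    kwargs["groove_plane"] = Plane(
        origin=_mirror_point(gp.origin), normal=_mirror_point(gp.normal),
        u=gp.u.copy(),
    )
    kwargs["shaft_axis"] = mir_axis(gt.shaft_axis)
    kwargs["tea"] = mir_axis(gt.tea)
    kwargs["pca"] = mir_axis(gt.pca)
    kwargs["head_radius"] = gt.head_radius
    kwargs["side"] = "left"
    return GroundTruth(**kwargs)


def generate_femur(params: FemurParams | None = None) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Generate a watertight femur-like mesh and its ground truth.

    Left femurs are produced by mirroring a right femur across the
    sagittal plane; the ground truth is mirrored accordingly.
    """
    params = params or FemurParams()
    params.validate()
    right = replace(params, side="right")
    con = _Construction(right)

    pitch = params.voxel_pitch
    hc, hr = con.head_center, params.head_radius
    lo = np.array([
        min(-con.flange_halfwidth, hc[0] - hr) - 12.0,
        -params.condyle_radius_medial + params.condyle_center_y - 12.0,
        params.condyle_center_z - params.condyle_z_drop_medial
        - max(params.condyle_radius_medial, params.condyle_radius_lateral) - 8.0,
    ])
    hi = np.array([
        max(con.flange_halfwidth, params.condyle_separation / 2 + params.condyle_radius_lateral + 12.0,
            hc[0] + hr + 8.0),
        max(30.0, hc[1] + hr + 8.0),
        hc[2] + hr + 8.0,
    ])
    nx, ny, nz = [int(np.ceil((hi[i] - lo[i]) / pitch)) + 1 for i in range(3)]
    xs = (lo[0] + pitch * np.arange(nx)).astype(np.float32)
    ys = (lo[1] + pitch * np.arange(ny)).astype(np.float32)
    zs = (lo[2] + pitch * np.arange(nz)).astype(np.float32)

    # two-stage sampling: a coarse pass locates the surface shell, the
    # exact field is then evaluated only there (the field is ~1-Lipschitz)
    stride = 4
    cx, cy_, cz = xs[::stride], ys[::stride], zs[::stride]
    gx, gy, gz = np.meshgrid(cx, cy_, cz, indexing="ij")
    coarse = con.field(gx.ravel(), gy.ravel(), gz.ravel()).reshape(gx.shape)
    vol = np.repeat(np.repeat(np.repeat(coarse, stride, 0), stride, 1), stride, 2)
    vol = vol[:nx, :ny, :nz]
    shell = np.abs(vol) < 3.0 * stride * pitch
    ii, jj, kk = np.nonzero(shell)
    vol[ii, jj, kk] = con.field(xs[ii], ys[jj], zs[kk])

    verts, faces, _, _ = measure.marching_cubes(vol, level=0.0, spacing=(pitch, pitch, pitch))
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    truth = con.ground_truth()
    if params.side == "left":
        v = mesh.vertices * np.array([-1.0, 1.0, 1.0])
        # topology is already welded; re-processing could degrade it
        mesh = trimesh.Trimesh(vertices=v, faces=mesh.faces[:, ::-1], process=False)
        truth = _mirror_truth(truth)
    return mesh, truth


def perturb_mesh(mesh: trimesh.Trimesh, sigma: float, seed: int) -> trimesh.Trimesh:
    """Displace vertices along their normals by zero-mean Gaussian noise."""
    if sigma < 0:
        raise ParameterError("sigma must be non-negative")
    out = mesh.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=len(mesh.vertices))
    out.vertices = mesh.vertices + mesh.vertex_normals * noise[:, None]
    return out


def sample_params(seed: int, side: str = "right") -> FemurParams:
    """Draw one plausible femur from jittered default dimensions."""
    rng = np.random.default_rng(seed)
    r_lat = rng.uniform(19.0, 21.5)
    return FemurParams(
        side=side,
        head_radius=rng.uniform(22.0, 26.5),
        neck_angle=rng.uniform(122.0, 132.0),
        shaft_length=rng.uniform(340.0, 380.0),
        shaft_radius=rng.uniform(13.0, 15.0),
        shaft_bow=rng.uniform(2.5, 5.5),
        shaft_bow_ap=rng.uniform(3.5, 6.5),
        condyle_radius_lateral=r_lat,
        condyle_radius_medial=r_lat + rng.uniform(0.5, 2.0),
        condyle_separation=rng.uniform(38.0, 43.0),
        epicondylar_twist_deg=rng.uniform(3.0, 8.0),
        groove_depth=rng.uniform(5.0, 7.0),
        ridge_saddle_height=rng.uniform(17.5, 19.0),
        ridge_drop=rng.uniform(4.5, 6.0),
        ridge_high_low_span=rng.uniform(13.0, 15.5),
        rng_seed=seed,
    )
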