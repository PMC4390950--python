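from types import SimpleNamespace

import numpy as np
import pytest
import trimesh
from shapely.geometry import Polygon

from femplan.geometry import Plane
from femplan.placement import PlacementConfig
from femplan.resection import (
    FootprintError,
    Footprint2D,
    compute_fit,
    detect_notching,
    flatten_contour,
    intersect_mesh_plane,
    measure_thicknesses,
    refine_size,
)


def _plane_z(z):
    return Plane(origin=[0, 0, z], normal=[0, 0, 1.0], u=[1.0, 0, 0])


# ------------------------------------------------------------------ contours


def test_cube_section_is_unit_square():
    cube = trimesh.creation.box(extents=[1, 1, 1])
    contour = intersect_mesh_plane(cube, _plane_z(0.25))
    assert len(contour.loops) == 1
    assert not contour.open_segments
    loop = contour.loops[0]
    assert np.allclose(loop[0], loop[-1])
    perim = np.linalg.norm(np.diff(loop, axis=0), axis=1).sum()
    assert perim == pytest.approx(4.0, abs=1e-9)
    fp = flatten_contour(contour)
    assert fp.area == pytest.approx(1.0, abs=1e-9)


def test_sphere_section_matches_circle_of_section():
    """Plane at height h cuts a circle of radius sqrt(R^2 - h^2)."""
    R, h = 20.0, 5.0
    sphere = trimesh.creation.uv_sphere(radius=R, count=[180, 360])
    contour = intersect_mesh_plane(sphere, _plane_z(h))
    fp = flatten_contour(contour)
    expected = np.pi * (R * R - h * h)
    assert abs(fp.area - expected) / expected < 1e-3
    radii = np.linalg.norm(contour.loops[0][:, :2], axis=1)
    assert abs(radii.mean() - np.sqrt(R * R - h * h)) / np.sqrt(R * R - h * h) < 1e-3


def test_plane_missing_mesh_gives_empty_contour():
    cube = trimesh.creation.box(extents=[1, 1, 1])
    contour = intersect_mesh_plane(cube, _plane_z(5.0))
    assert contour.loops == [] and contour.open_segments == []
    with pytest.raises(FootprintError):
        flatten_contour(contour)


def _annular_prism():
    """Square tube: outer 4x4, inner 2x2 hole, z in [0, 2] — watertight."""
    out_sq = np.array([[-2, -2], [2, -2], [2, 2], [-2, 2]], float)
    in_sq = 0.5 * out_sq
    verts = []
    for z in (0.0, 2.0):
        for p in out_sq:
            verts.append([p[0], p[1], z])
        for p in in_sq:
            verts.append([p[0], p[1], z])
    verts = np.array(verts)
    # layout: 0-3 outer z=0, 4-7 inner z=0, 8-11 outer z=2, 12-15 inner z=2
    mesh_faces = []
    for i in range(4):
        j = (i + 1) % 4
        mesh_faces += [[i, j, 8 + j], [i, 8 + j, 8 + i]]                  # outer wall
        mesh_faces += [[4 + j, 4 + i, 12 + i], [4 + j, 12 + i, 12 + j]]   # inner wall
        mesh_faces += [[j, i, 4 + i], [j, 4 + i, 4 + j]]                  # bottom annulus
        mesh_faces += [[8 + i, 8 + j, 12 + j], [8 + i, 12 + j, 12 + i]]   # top annulus
    return trimesh.Trimesh(vertices=verts, faces=np.array(mesh_faces), process=False)


def test_contour_with_hole_area_outer_minus_inner():
    prism = _annular_prism()
    from femplan.mesh_io import validate_watertight

    assert validate_watertight(prism).watertight
    contour = intersect_mesh_plane(prism, _plane_z(1.0))
    assert len(contour.loops) == 2
    fp = flatten_contour(contour)
    assert fp.area == pytest.approx(16.0 - 4.0, abs=1e-9)


def test_open_segments_on_non_watertight_mesh():
    cube = trimesh.creation.box(extents=[1, 1, 1])
    # remove the two triangles of one side wall to open the cut path
    keep = ~np.all(np.isclose(cube.triangles[:, :, 0], 0.5), axis=1)
    holed = trimesh.Trimesh(vertices=cube.vertices, faces=cube.faces[keep], process=False)
    contour = intersect_mesh_plane(holed, _plane_z(0.0))
    assert len(contour.open_segments) >= 1
    assert not contour.loops


# ----------------------------------------------------------------------- fit


def _square_fp(side, cx=0.0, cy=0.0):
    h = side / 2
    poly = Polygon([(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)])
    return Footprint2D(plane=_plane_z(0), polygons=[poly], area=poly.area)


def test_fit_identical_squares_zero():
    rep = compute_fit(_square_fp(20), _square_fp(20))
    assert rep.max_overhang == pytest.approx(0.0, abs=1e-9)
    assert rep.max_underhang == pytest.approx(0.0, abs=1e-9)


def test_fit_overhang_offset_rectangles():
    rep = compute_fit(_square_fp(20), _square_fp(24))
    assert rep.max_overhang == pytest.approx(2.0, abs=1e-9)
    assert rep.max_underhang == pytest.approx(0.0, abs=1e-9)


def test_fit_underhang_wide_bone():
    bone = Footprint2D(plane=_plane_z(0),
                       polygons=[Polygon([(-13, -10), (13, -10), (13, 10), (-13, 10)])])
    rep = compute_fit(bone, _square_fp(20))
    assert rep.max_underhang == pytest.approx(3.0, abs=1e-9)
    assert rep.max_overhang == pytest.approx(0.0, abs=1e-9)


def test_fit_antisymmetric_on_convex_polygons():
    a, b = _square_fp(20), _square_fp(26)
    r1 = compute_fit(a, b)
    r2 = compute_fit(b, a)
    assert r1.max_overhang == pytest.approx(r2.max_underhang, abs=1e-9)
    assert r1.max_underhang == pytest.approx(r2.max_overhang, abs=1e-9)


def test_fit_empty_polygon_errors():
    with pytest.raises(FootprintError):
        compute_fit(Footprint2D(plane=_plane_z(0)), _square_fp(20))


# -------------------------------------------------------------- refine_size


def _stub_family(n=5):
    sizes = [SimpleNamespace(label=str(i + 1), ap_height=40.0 + 4 * i) for i in range(n)]
    return SimpleNamespace(sizes=sizes)


def _table_evaluator(table):
    def ev(size):
        oh, uh = table[size.label]
        return SimpleNamespace(max_overhang=oh, max_underhang=uh)
    return ev


def test_refine_downsizes_once_on_overhang():
    fam = _stub_family()
    table = {"3": (2.0, 0.0), "2": (1.0, 1.0)}
    final, trace = refine_size(fam, fam.sizes[2], _table_evaluator(table), PlacementConfig())
    assert final.label == "2"
    assert not trace["unsatisfiable"]
    assert [s for s, _, _ in trace["steps"]] == ["3", "2"]


def test_refine_keeps_size_within_thresholds():
    fam = _stub_family()
    table = {"3": (1.0, 1.5)}
    final, trace = refine_size(fam, fam.sizes[2], _table_evaluator(table), PlacementConfig())
    assert final.label == "3"
    assert len(trace["steps"]) == 1


def test_refine_upsizes_on_underhang():
    fam = _stub_family()
    table = {"2": (0.0, 2.5), "3": (0.5, 1.0)}
    final, trace = refine_size(fam, fam.sizes[1], _table_evaluator(table), PlacementConfig())
    assert final.label == "3"


def test_refine_oscillation_prefers_overhang_safe_size():
    """OH at size k, UH at size k-1: pick k-1 (overhang priority), flag it."""
    fam = _stub_family()
    table = {"3": (2.0, 0.0), "2": (0.0, 2.5)}
    final, trace = refine_size(fam, fam.sizes[2], _table_evaluator(table), PlacementConfig())
    assert final.label == "2"
    assert trace["unsatisfiable"]


def test_refine_terminates_and_never_revisits():
    fam = _stub_family(6)
    table = {s.label: (5.0, 0.0) for s in fam.sizes}  # everything overhangs
    calls = []
    ev = _table_evaluator(table)

    def counting(size):
        calls.append(size.label)
        return ev(size)

    final, trace = refine_size(fam, fam.sizes[5], counting, PlacementConfig())
    assert len(calls) == len(set(calls)) <= len(fam.sizes)
    assert trace["unsatisfiable"]
    # the chosen size attains the minimal overhang among visited sizes
    assert table[final.label][0] == min(table[l][0] for l in calls)


def test_refine_threshold_edges():
    fam = _stub_family()
    cfg = PlacementConfig()
    ok, _ = refine_size(fam, fam.sizes[2],
                        _table_evaluator({"3": (1.49, 1.99)}), cfg)
    assert ok.label == "3"
    moved, _ = refine_size(fam, fam.sizes[2],
                           _table_evaluator({"3": (1.51, 0.0), "2": (0.0, 0.0)}), cfg)
    assert moved.label == "2"


# ------------------------------------------------------------- thicknesses


def _lm(**kw):
    base = {k: np.zeros(3) for k in (
        "anterior_lateral", "anterior_medial", "posterior_lateral",
        "posterior_medial", "distal_lateral", "distal_medial")}
    base.update(kw)
    return SimpleNamespace(**base)


def _planes(distal=None, anterior=None, posterior=None):
    far = Plane(origin=[0, 0, -1e6], normal=[0, 0, 1.0])
    return SimpleNamespace(distal=distal or far, anterior=anterior or far,
                           posterior=posterior or far,
                           plane=lambda n: None)


def test_thickness_hemisphere_cap():
    """A plane 8.2 mm below a condylar pole resects 8.2 mm at that point."""
    pole = np.array([0.0, 0.0, 0.0])
    distal = Plane(origin=[0, 0, 8.2], normal=[0, 0, 1.0])  # inward = proximal
    th = measure_thicknesses(_planes(distal=distal), _lm(distal_medial=pole,
                                                         distal_lateral=pole))
    assert th.FDCM == pytest.approx(8.2, abs=1e-12)


def test_thickness_tangent_plane_zero_and_retained_side_zero():
    pole = np.zeros(3)
    tangent = Plane(origin=[0, 0, 0], normal=[0, 0, 1.0])
    th = measure_thicknesses(_planes(distal=tangent), _lm(distal_medial=pole))
    assert th.FDCM == 0.0
    above = Plane(origin=[0, 0, -3.0], normal=[0, 0, 1.0])
    th2 = measure_thicknesses(_planes(distal=above), _lm(distal_medial=pole))
    assert th2.FDCM == 0.0  # landmark on the retained side: nothing resected


def test_thickness_totals_identity(default_femur, default_axes, family, default_profile):
    from femplan.cortex import compute_frac_point
    from femplan.placement import build_resection_planes

    mesh, _ = default_femur
    cfg = PlacementConfig()
    cp = compute_frac_point(mesh, default_axes.frame, default_axes, family.sizes[3],
                            cfg, profile=default_profile, landmarks=default_axes.landmarks)
    planes = build_resection_planes(mesh, default_axes, family.sizes[3], cp.frac_point, cfg)
    th = measure_thicknesses(planes, default_axes.landmarks)
    assert th.total_lateral == pytest.approx(th.FACL + th.FPCL, abs=1e-12)
    assert th.total_medial == pytest.approx(th.FACM + th.FPCM, abs=1e-12)
    assert all(v >= 0 for v in (th.FACL, th.FPCL, th.FACM, th.FPCM, th.FDCL, th.FDCM))


# ---------------------------------------------------------------- notching


def _flat_cortex_frame():
    frame = SimpleNamespace(origin=np.zeros(3), PD=np.array([0, 0, 1.0]),
                            AP=np.array([0, 1.0, 0]), ML=np.array([1.0, 0, 0]))
    box = trimesh.creation.box(extents=[20, 10, 60])  # cortex slab, front at y=5
    for _ in range(3):
        box = box.subdivide()  # detect_notching probes vertices
    return box, frame


def test_notch_plane_anterior_of_cortex_is_clean():
    mesh, frame = _flat_cortex_frame()
    plane = Plane(origin=[0, 6.0, 0], normal=[0, -1.0, 0])  # inward posterior
    rep = detect_notching(mesh, plane, flange_proximal_extent=0.0, frame=frame)
    assert not rep.notched and rep.notch_depth == 0.0


def test_notch_depth_of_posteriorised_plane_is_one_mm():
    mesh, frame = _flat_cortex_frame()
    plane = Plane(origin=[0, 4.0, 0], normal=[0, -1.0, 0])  # 1 mm into the cortex
    rep = detect_notching(mesh, plane, flange_proximal_extent=0.0, frame=frame)
    assert rep.notched
    assert rep.notch_depth == pytest.approx(1.0, abs=1e-9)
    assert rep.notch_location is not None


def test_notch_gate_filters_numerical_noise():
    mesh, frame = _flat_cortex_frame()
    plane = Plane(origin=[0, 4.99, 0], normal=[0, -1.0, 0])
    rep = detect_notching(mesh, plane, flange_proximal_extent=0.0, frame=frame)
    assert not rep.notched
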