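import numpy as np
import pytest
import trimesh

from femplan import axes as A
from femplan.geometry import Axis3D, Plane, angle_between_deg, distance_to_surface, unit
from femplan.synthetic import FemurParams, generate_femur, perturb_mesh


# --------------------------------------------------------------------- sphere


def test_fit_sphere_exact():
    rng = np.random.default_rng(0)
    d = rng.normal(size=(500, 3))
    d /= np.linalg.norm(d, axis=1)[:, None]
    center, radius, rms = A.fit_sphere(d * 25.0)
    assert np.allclose(center, 0, atol=1e-9)
    assert radius == pytest.approx(25.0, abs=1e-9)
    assert rms < 1e-9


def test_fit_sphere_matches_circumsphere_of_four_points():
    pts = np.array([[0, 0, 0], [4, 0, 0], [0, 6, 0], [0, 0, 8.0]])
    center, radius, _ = A.fit_sphere(pts)
    # independent 4x4 linear-system circumsphere
    M = np.column_stack([2 * pts, np.ones(4)])
    b = (pts ** 2).sum(axis=1)
    sol = np.linalg.solve(M, b)
    c_ref = sol[:3]
    r_ref = np.sqrt(sol[3] + c_ref @ c_ref)
    assert np.allclose(center, c_ref, atol=1e-9)
    assert radius == pytest.approx(r_ref, abs=1e-9)


def test_fit_sphere_noisy_monte_carlo():
    rng = np.random.default_rng(42)
    d = rng.normal(size=(2000, 3))
    d /= np.linalg.norm(d, axis=1)[:, None]
    r = 25.0 + rng.normal(0, 0.1, size=2000)
    center, _, _ = A.fit_sphere(d * r[:, None] + [3.0, -2.0, 1.0])
    assert np.linalg.norm(center - [3.0, -2.0, 1.0]) < 0.05


def test_fit_sphere_degenerate_inputs():
    with pytest.raises(A.DegenerateFitError):
        A.fit_sphere(np.zeros((3, 3)))
    coplanar = np.column_stack([np.random.default_rng(1).normal(size=(50, 2)),
                                np.zeros(50)])
    with pytest.raises(A.DegenerateFitError):
        A.fit_sphere(coplanar)


# ----------------------------------------------------------------- head centre


def test_head_center_default(default_femur, default_axes):
    _, truth = default_femur
    assert np.linalg.norm(default_axes.head_center - truth.head_center) < 0.5


def test_head_center_perturbed(default_femur):
    mesh, truth = default_femur
    noisy = perturb_mesh(mesh, 0.2, seed=4)
    frame = A.anatomical_frame(noisy)
    hc = A.compute_head_center(noisy, frame)
    assert np.linalg.norm(hc - truth.head_center) < 1.0


def test_head_center_missing_head_errors(default_femur):
    mesh, _ = default_femur
    v = mesh.vertices.view(np.ndarray)
    mid = 0.5 * (v[:, 2].min() + v[:, 2].max())
    cropped = mesh.slice_plane([0, 0, mid], [0, 0, -1.0])
    frame = A.AnatomicalFrame(origin=np.array([0, 0, 0.0]),
                              ML=np.array([1, 0, 0.0]),
                              AP=np.array([0, 1, 0.0]),
                              PD=np.array([0, 0, 1.0]))
    with pytest.raises(A.LandmarkError):
        A.compute_head_center(cropped, frame)


# ------------------------------------------------------------------------ DAA


def _identity_frame():
    return A.AnatomicalFrame(origin=np.zeros(3), ML=np.array([1.0, 0, 0]),
                             AP=np.array([0, 1.0, 0]), PD=np.array([0, 0, 1.0]))


def test_daa_straight_cylinder_phantom():
    cyl = trimesh.creation.cylinder(radius=14.0, height=300.0, sections=64)
    axis = A.compute_daa(cyl, _identity_frame())
    assert angle_between_deg(axis.direction, [0, 0, 1.0]) < 0.1


def test_daa_zero_bow_matches_truth():
    mesh, truth = generate_femur(FemurParams(shaft_bow=0.0, shaft_bow_ap=0.0))
    frame = A.anatomical_frame(mesh)
    axis = A.compute_daa(mesh, frame)
    assert angle_between_deg(axis.direction, truth.shaft_axis.direction) < 0.1


def test_daa_bowed_matches_dense_sectioning_oracle(default_femur):
    mesh, _ = default_femur
    frame = A.anatomical_frame(mesh)
    axis = A.compute_daa(mesh, frame, spacing=2.0)
    oracle = A.compute_daa(mesh, frame, spacing=1.0)
    assert angle_between_deg(axis.direction, oracle.direction) < 0.2


def test_daa_too_few_sections_errors():
    small = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    with pytest.raises(A.DegenerateAxisError):
        A.compute_daa(small, _identity_frame())


# ------------------------------------------------------------------ landmarks


def test_condylar_landmarks_within_tolerance(default_femur, default_axes):
    _, truth = default_femur
    for name, pt in default_axes.landmarks.as_dict().items():
        err = np.linalg.norm(pt - getattr(truth, name))
        assert err < 1.0, f"{name}: {err:.2f} mm"


def test_landmarks_equivariant_under_rigid_rotation(default_femur):
    mesh, _ = default_femur
    frame = A.anatomical_frame(mesh)
    lm = A.compute_condylar_landmarks(mesh, frame)
    R = trimesh.transformations.rotation_matrix(np.deg2rad(30), unit([1, 2, 3.0]))
    rotated = mesh.copy()
    rotated.apply_transform(R)
    frame_r = A.anatomical_frame(rotated)
    lm_r = A.compute_condylar_landmarks(rotated, frame_r)
    for name, pt in lm.as_dict().items():
        expected = (R[:3, :3] @ pt) + R[:3, 3]
        assert np.linalg.norm(lm_r.as_dict()[name] - expected) < 1e-3, name


# ----------------------------------------------------------------- knee centre


def test_knee_center_line_plane_example():
    tea = Axis3D(point=[0, 0, 0], direction=[1, 0, 0])
    plane = Plane(origin=[10, 0, 0], normal=[1, 0, 0])
    assert np.allclose(A.compute_knee_center(tea, plane), [10, 0, 0])


def test_knee_center_synthetic(default_femur, default_axes):
    _, truth = default_femur
    assert np.linalg.norm(default_axes.knee_center - truth.knee_center) < 1.5


def test_knee_center_parallel_errors():
    tea = Axis3D(point=[0, 1, 0], direction=[0, 1, 0])
    plane = Plane(origin=[10, 0, 0], normal=[1, 0, 0])
    with pytest.raises(A.LandmarkError):
        A.compute_knee_center(tea, plane)


# ------------------------------------------------------------------- axis set


def test_axis_set_pca3_exactly_three_degrees(default_axes):
    assert A.angle_3d(default_axes.PCA, default_axes.PCA_plus3) == pytest.approx(3.0, abs=1e-6)


def test_pca3_rotated_towards_tea(default_axes):
    before = A.angle_3d(default_axes.PCA, default_axes.TEA)
    after = A.angle_3d(default_axes.PCA_plus3, default_axes.TEA)
    assert after < before


def test_daa_exit_point_on_surface(default_femur, default_axes):
    mesh, _ = default_femur
    d = distance_to_surface(mesh, [default_axes.daa_exit_point])
    assert d[0] < 0.1


def test_axes_recovered_against_truth(default_femur, default_axes):
    _, truth = default_femur
    assert angle_between_deg(default_axes.TEA.direction, truth.tea.direction) < 0.5
    assert angle_between_deg(default_axes.PCA.direction, truth.pca.direction) < 0.5
    assert angle_between_deg(default_axes.DAA.direction, truth.shaft_axis.direction) < 0.5


def test_ma1_equals_ma2_when_knee_center_is_exit_point(default_axes):
    head = default_axes.head_center
    exit_pt = default_axes.daa_exit_point
    ma1 = Axis3D(point=exit_pt, direction=head - exit_pt)
    ma2 = Axis3D(point=exit_pt, direction=head - exit_pt)
    assert A.angle_3d(ma1, ma2) < 1e-9


# --------------------------------------------------------------------- angles


def test_angle_3d_examples():
    e = Axis3D(point=np.zeros(3), direction=[1, 0, 0])
    assert A.angle_3d(e, e) == pytest.approx(0.0, abs=1e-12)
    assert A.angle_3d(e, Axis3D(np.zeros(3), [0, 1, 0])) == pytest.approx(90.0)
    diag = Axis3D(np.zeros(3), [1, 1, 0])
    assert A.angle_3d(e, diag) == pytest.approx(45.0, abs=1e-9)


@pytest.mark.parametrize("fe_true,vv_true", [(5.0, 0.0), (0.0, 3.0), (4.0, 2.0), (-2.5, 1.5)])
def test_decompose_fe_vv_matches_rotation_compose_oracle(fe_true, vv_true):
    """Composed ML/AP rotations decompose back within 1e-6 degrees."""
    frame = _identity_frame()
    from femplan.geometry import rotation_about_axis

    a = Axis3D(np.zeros(3), [0, 0, 1.0])
    R = rotation_about_axis(frame.AP, vv_true) @ rotation_about_axis(frame.ML, fe_true)
    b = Axis3D(np.zeros(3), R @ a.direction)
    fe, vv = A.decompose_fe_vv(a, b, frame)
    # independent projection oracle
    d = b.direction
    fe_ref = np.degrees(np.arctan2(-d[1], d[2]))
    vv_ref = np.degrees(np.arctan2(d[0], d[2]))
    assert fe == pytest.approx(fe_ref, abs=1e-6)
    assert vv == pytest.approx(vv_ref, abs=1e-6)
    if vv_true == 0.0:
        assert fe == pytest.approx(fe_true, abs=1e-6)
    if fe_true == 0.0:
        assert vv == pytest.approx(vv_true, abs=1e-6)


def test_decompose_degenerate_errors():
    frame = _identity_frame()
    a = Axis3D(np.zeros(3), frame.ML)
    with pytest.raises(A.DecompositionError):
        A.decompose_fe_vv(a, a, frame)


def test_angle_report_signed_directions(default_axes):
    rep = A.angle_report(default_axes)
    # MA-2 exits anterior of the knee centre: more flexed than MA-1
    assert rep.signed["ma1_ma2_fe"] > 0
    # the DAA leans lateral-proximally: more valgus than MA-1
    assert rep.signed["ma1_daa_vv"] > 0
    for v in (rep.pca_tea, rep.ma1_daa_fe, rep.ma1_daa_vv, rep.ma1_ma2_fe, rep.ma1_ma2_vv):
        assert 0.0 <= v <= 90.0
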