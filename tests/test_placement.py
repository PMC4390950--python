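import numpy as np
import pytest
import trimesh

from femplan import axes as A
from femplan.geometry import Axis3D, angle_between_deg, rotation_about_axis, unit
from femplan.placement import (
    PlacementConfig,
    apply_cartilage_offset,
    build_resection_planes,
    compute_bone_ap_height,
)


def test_config_defaults_follow_protocol():
    cfg = PlacementConfig()
    assert cfg.distal_offset == 10.0
    assert cfg.cartilage_offset == 1.8
    assert cfg.overhang_threshold == 1.5
    assert cfg.underhang_threshold == 2.0


def test_config_validation():
    with pytest.raises(ValueError):
        PlacementConfig(longitudinal_axis="MA7")
    with pytest.raises(ValueError):
        PlacementConfig(distal_offset=-1.0)


def test_cartilage_offset_examples():
    axis = Axis3D(point=np.zeros(3), direction=[0, 0, 1.0])
    p = np.zeros(3)
    assert np.allclose(apply_cartilage_offset(p, axis, 0.0), p)
    assert np.allclose(apply_cartilage_offset(p, axis, 1.8), [0, 0, -1.8])
    twice = apply_cartilage_offset(apply_cartilage_offset(p, axis, 0.9), axis, 0.9)
    assert np.allclose(twice, apply_cartilage_offset(p, axis, 1.8))


@pytest.fixture(scope="module")
def planes_default(default_femur, default_axes, default_profile, family):
    mesh, _ = default_femur
    from femplan.cortex import compute_frac_point

    cfg = PlacementConfig()
    cp = compute_frac_point(mesh, default_axes.frame, default_axes, family.sizes[3],
                            cfg, profile=default_profile, landmarks=default_axes.landmarks)
    planes = build_resection_planes(mesh, default_axes, family.sizes[3],
                                    cp.frac_point, cfg)
    return cfg, cp, planes


def test_distal_plane_offset_is_ten_mm(default_axes, planes_default):
    cfg, _, planes = planes_default
    L = default_axes.MA1.direction
    if np.dot(L, default_axes.frame.PD) < 0:
        L = -L
    cart = apply_cartilage_offset(default_axes.most_distal_point, L, cfg.cartilage_offset)
    assert planes.distal.signed_distance(cart)[0] == pytest.approx(-10.0, abs=1e-9)
    # the virtual cartilage point itself sits 1.8 mm distal of the bony point
    assert np.linalg.norm(cart - default_axes.most_distal_point) == pytest.approx(1.8)


def test_distal_plane_normal_parallel_to_axis(default_axes, planes_default):
    _, _, planes = planes_default
    ang = angle_between_deg(planes.distal.normal, default_axes.MA1.direction)
    assert ang < 1e-6


def test_anterior_plane_contains_reference(planes_default):
    _, cp, planes = planes_default
    assert abs(planes.anterior.signed_distance(cp.frac_point)[0]) < 1e-6


def test_pca_vs_pca3_poses_differ_by_projected_rotation(default_femur, default_axes,
                                                        planes_default, family):
    mesh, _ = default_femur
    _, cp, _ = planes_default
    size = family.sizes[3]
    p1 = build_resection_planes(mesh, default_axes, size, cp.frac_point,
                                PlacementConfig(rotation_reference="PCA"))
    p2 = build_resection_planes(mesh, default_axes, size, cp.frac_point,
                                PlacementConfig(rotation_reference="PCA3"))
    R1, R2 = p1.implant_pose[:3, :3], p2.implant_pose[:3, :3]
    dR = R1.T @ R2
    angle = np.degrees(np.arccos(np.clip((np.trace(dR) - 1) / 2, -1, 1)))
    # independent oracle: angle between the two references projected
    # perpendicular to the longitudinal axis
    L = p1.implant_pose[:3, 2]
    def proj(d):
        return unit(d - np.dot(d, L) * L)
    oracle = angle_between_deg(proj(default_axes.PCA.direction),
                               proj(default_axes.PCA_plus3.direction))
    assert angle == pytest.approx(oracle, abs=1e-9)
    assert oracle == pytest.approx(3.0, abs=0.05)
    # the relative rotation is about the longitudinal axis
    rotvec_axis = np.array([dR[2, 1] - dR[1, 2], dR[0, 2] - dR[2, 0], dR[1, 0] - dR[0, 1]])
    assert angle_between_deg(rotvec_axis, [0, 0, 1.0]) < 1e-6


def test_ma1_to_ma2_changes_pose_flexion_by_fe_angle(default_femur, default_axes,
                                                     planes_default, family):
    mesh, _ = default_femur
    _, cp, p1 = planes_default
    size = family.sizes[3]
    p2 = build_resection_planes(mesh, default_axes, size, cp.frac_point,
                                PlacementConfig(longitudinal_axis="MA2"))
    fe, _ = A.decompose_fe_vv(default_axes.MA1, default_axes.MA2, default_axes.frame)
    z1 = Axis3D(np.zeros(3), p1.implant_pose[:3, 2])
    z2 = Axis3D(np.zeros(3), p2.implant_pose[:3, 2])
    fe_pose, _ = A.decompose_fe_vv(z1, z2, default_axes.frame)
    assert fe_pose == pytest.approx(fe, abs=1e-6)


def test_placement_equivariant_under_rigid_transform(default_femur, default_axes,
                                                     planes_default, family):
    mesh, _ = default_femur
    cfg, cp, p_ref = planes_default
    R = trimesh.transformations.rotation_matrix(np.deg2rad(25), unit([0.3, 1.0, 0.2]),
                                                point=[5.0, -3.0, 10.0])
    rotated = mesh.copy()
    rotated.apply_transform(R)
    axes_r = A.build_axis_set(rotated)
    Rm, t = R[:3, :3], R[:3, 3]
    frac_r = Rm @ cp.frac_point + t
    p_rot = build_resection_planes(rotated, axes_r, family.sizes[3], frac_r, cfg)
    for name in ("distal", "anterior", "posterior"):
        n_expect = Rm @ p_ref.plane(name).normal
        # planes equal up to landmark re-detection noise on the rotated mesh
        assert angle_between_deg(p_rot.plane(name).normal, n_expect) < 0.2
        d_expect = np.dot(n_expect, Rm @ p_ref.plane(name).origin + t)
        d_got = np.dot(p_rot.plane(name).normal, p_rot.plane(name).origin)
        assert abs(d_got - d_expect) < 0.5


def test_bone_ap_height_linearity_and_symmetry(default_axes):
    frame = default_axes.frame
    lm = default_axes.landmarks
    ref = np.asarray(default_axes.landmarks.anterior_lateral, float)
    posterior = (lm.posterior_medial, lm.posterior_lateral)
    h0 = compute_bone_ap_height(frame, ref, posterior)
    h1 = compute_bone_ap_height(frame, ref + 2.0 * frame.AP, posterior)
    assert h1 - h0 == pytest.approx(2.0, abs=1e-9)
    # symmetric posterior points give the same result either way round
    p = lm.posterior_medial
    h_same = compute_bone_ap_height(frame, ref, (p, p))
    assert h_same == compute_bone_ap_height(frame, ref, (p,))


def test_bone_ap_height_matches_construction(default_femur, default_axes):
    _, truth = default_femur
    frame = default_axes.frame
    h = compute_bone_ap_height(frame, truth.saddle,
                               (truth.posterior_medial, truth.posterior_lateral))
    # AP extent from the saddle to the deeper posterior condyle, by construction
    expected = float((truth.saddle - frame.origin) @ frame.AP) - min(
        float((truth.posterior_medial - frame.origin) @ frame.AP),
        float((truth.posterior_lateral - frame.origin) @ frame.AP))
    assert h == pytest.approx(expected, abs=1e-9)
    assert 40.0 < h < 60.0
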