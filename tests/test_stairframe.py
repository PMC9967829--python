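"""Stair-frame construction: plane fit, basis, homogeneous transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stairwatch import (
    build_basis,
    build_transform,
    fit_wall_plane,
    handrail_axis,
    to_stair_frame,
)
from stairwatch.scene import SceneSpec, TraversalSpec, simulate_traversal
from stairwatch.stairframe import (
    CalibrationError,
    DegenerateFitError,
    StairFrame,
    orient_normal_toward_camera,
)


def _random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


# --- handrail axis

def test_handrail_axis_examples():
    np.testing.assert_allclose(handrail_axis([0, 0, 0], [1000, 0, 0]), [1, 0, 0])
    np.testing.assert_allclose(
        handrail_axis([0, 0, 0], [1000, 0, -1000]),
        [1 / np.sqrt(2), 0, -1 / np.sqrt(2)],
    )


def test_handrail_axis_degenerate():
    with pytest.raises(CalibrationError):
        handrail_axis([0, 0, 0], [5, 0, 0])


# --- wall plane fit

def test_fit_frontal_wall():
    rng = np.random.default_rng(0)
    xy = rng.uniform(-500, 500, (200, 2))
    pts = np.column_stack([xy, np.full(200, 2000.0)])
    fit = fit_wall_plane(pts)
    assert abs(fit.a) < 1e-9 and abs(fit.b) < 1e-9
    assert fit.d == pytest.approx(-2000.0)
    np.testing.assert_allclose(fit.normal, [0, 0, 1], atol=1e-9)
    assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)


def test_fit_analytic_oblique_plane():
    # Z = -X + 3000  <=>  1*X + 0*Y + Z - 3000 = 0
    rng = np.random.default_rng(1)
    xy = rng.uniform(-500, 500, (200, 2))
    pts = np.column_stack([xy[:, 0], xy[:, 1], -xy[:, 0] + 3000.0])
    fit = fit_wall_plane(pts)
    assert fit.a == pytest.approx(1.0) and fit.b == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(fit.normal, np.array([1, 0, 1]) / np.sqrt(2), atol=1e-9)


def test_fit_collinear_cloud_rejected():
    t = np.linspace(0, 1, 50)
    pts = np.column_stack([t, 2 * t, 3 * t])
    with pytest.raises(DegenerateFitError):
        fit_wall_plane(pts)


def test_fit_recovers_noisy_random_normals():
    rng = np.random.default_rng(7)
    for _ in range(20):
        # wall normal within the camera-visible cone of the optical axis
        n = np.array([rng.uniform(-0.6, 0.6), rng.uniform(-0.6, 0.6), 1.0])
        n /= np.linalg.norm(n)
        e1 = np.cross(n, [0, 0, 1.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        ab = rng.uniform(-500, 500, (1000, 2))
        pts = 2500.0 * np.array([0, 0, 1.0]) + ab @ np.vstack([e1, e2])
        pts[:, 2] += rng.normal(0, 5.0, 1000)
        fit = fit_wall_plane(pts)
        cos = abs(float(fit.normal @ n))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0


def test_orient_normal_toward_camera():
    n = orient_normal_toward_camera(np.array([0, 0, 1.0]), cloud_centroid=[0, 0, 2000.0])
    np.testing.assert_allclose(n, [0, 0, -1.0])
    n = orient_normal_toward_camera(np.array([0, 0, -1.0]), cloud_centroid=[0, 0, 2000.0])
    np.testing.assert_allclose(n, [0, 0, -1.0])


# --- basis

def test_build_basis_examples():
    nx, ny, nz = build_basis([1, 0, 0], [0, 1, 0])
    np.testing.assert_allclose(nz, [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(ny, [0, 1, 0], atol=1e-12)

    nx, ny, nz = build_basis([1, 0, 0], [0.6, 0.8, 0])
    np.testing.assert_allclose(ny, [0, 1, 0], atol=1e-12)
    np.testing.assert_allclose(nz, [0, 0, 1], atol=1e-12)


def test_build_basis_near_parallel_rejected():
    with pytest.raises(CalibrationError, match="deg"):
        build_basis([1, 0, 0], [0.999, 0.01, 0])


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_build_basis_gram_identity(seed):
    rng = np.random.default_rng(seed)
    a, b = rng.normal(size=3), rng.normal(size=3)
    if np.linalg.norm(a) < 1e-3 or np.linalg.norm(b) < 1e-3:
        return
    a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
    if abs(a @ b) >= 0.99:
        return
    basis = np.vstack(build_basis(a, b))
    np.testing.assert_allclose(basis @ basis.T, np.eye(3), atol=1e-9)
    assert np.linalg.det(basis) == pytest.approx(1.0, abs=1e-9)


# --- transform

def test_origin_maps_to_zero():
    rng = np.random.default_rng(3)
    frame = StairFrame(origin=rng.normal(0, 1000, 3), R=_random_rotation(rng))
    np.testing.assert_allclose(frame.apply(frame.origin), [0, 0, 0], atol=1e-9)


def test_identity_basis_translation():
    frame = build_transform((np.eye(3)[0], np.eye(3)[1], np.eye(3)[2]), [100, 0, 0])
    np.testing.assert_allclose(frame.apply([1100, 0, 0]), [1000, 0, 0])


def test_transform_inverse_round_trip():
    rng = np.random.default_rng(11)
    frame = StairFrame(origin=rng.normal(0, 2000, 3), R=_random_rotation(rng))
    pts = rng.normal(0, 3000, (100, 3))
    np.testing.assert_allclose(frame.invert(frame.apply(pts)), pts, atol=1e-6)


def test_homogeneous_matrix_matches_apply():
    rng = np.random.default_rng(5)
    frame = StairFrame(origin=rng.normal(0, 1000, 3), R=_random_rotation(rng))
    p = rng.normal(0, 1000, 3)
    q_h = frame.H @ np.append(p, 1.0)
    np.testing.assert_allclose(q_h[:3], frame.apply(p), atol=1e-9)
    assert q_h[3] == 1.0
    np.testing.assert_allclose(np.linalg.inv(frame.H)[:3, 3], frame.origin, atol=1e-6)


def test_non_orthonormal_basis_rejected():
    with pytest.raises(CalibrationError):
        build_transform((np.array([1, 0, 0]), np.array([0.5, 0.5, 0]), np.array([0, 0, 1])), [0, 0, 0])


# --- session transform

def test_identity_frame_flips_tag_only(stair_session_factory, intr):
    from stairwatch import Session, SkeletonFrame

    frames = [
        SkeletonFrame(timestamp=t, joints={"PELVIS": np.array([t * 100, 1.0, 2.0])})
        for t in range(5)
    ]
    session = Session(frames=frames, intrinsics=intr, space="camera")
    out = to_stair_frame(session, StairFrame(origin=np.zeros(3), R=np.eye(3)))
    assert out.space == "stair" and out.provenance is not None
    for f0, f1 in zip(session.frames, out.frames):
        np.testing.assert_allclose(f1.joint("PELVIS"), f0.joint("PELVIS"))
    with pytest.raises(ValueError, match="already in stair space"):
        to_stair_frame(out, StairFrame(origin=np.zeros(3), R=np.eye(3)))


def test_rigid_transform_preserves_distances():
    rng = np.random.default_rng(9)
    scene = SceneSpec()
    session, _ = simulate_traversal(scene, TraversalSpec(joint_noise_sd=5.0, seed=2))
    frame = StairFrame(origin=rng.normal(0, 1000, 3), R=_random_rotation(rng))
    out = to_stair_frame(session, frame)
    for f0, f1 in zip(session.frames[::10], out.frames[::10]):
        names = list(f0.joints)
        for a, b in zip(names, names[1:]):
            d0 = np.linalg.norm(f0.joint(a) - f0.joint(b))
            d1 = np.linalg.norm(f1.joint(a) - f1.joint(b))
            assert abs(d0 - d1) <= 1e-6


def test_ascent_pelvis_x_increasing(scene, true_frame):
    session, _ = simulate_traversal(scene, TraversalSpec(direction="up", speed=0.5))
    stair = to_stair_frame(session, true_frame)
    _, pelvis = stair.joint_trajectory("PELVIS")
    assert np.all(np.diff(pelvis[:, 0]) > 0)


def test_plane_fit_residual_rigid_invariance():
    rng = np.random.default_rng(21)
    xy = rng.uniform(-400, 400, (300, 2))
    pts = np.column_stack([xy, 0.2 * xy[:, 0] - 0.1 * xy[:, 1] + 2000.0])
    pts[:, 2] += rng.normal(0, 3.0, 300)
    fit0 = fit_wall_plane(pts)
    # a modest rotation keeps the moved wall camera-visible (c != 0)
    angle = np.radians(10)
    R = np.array(
        [[np.cos(angle), 0, np.sin(angle)], [0, 1, 0], [-np.sin(angle), 0, np.cos(angle)]]
    )
    moved = pts @ R.T + np.array([50.0, -30.0, 100.0])
    fit1 = fit_wall_plane(moved)
    # rms is measured along Z, so compare plane-orthogonal residuals
    orth0 = fit0.rms_residual * fit0.normal[2]
    orth1 = fit1.rms_residual * fit1.normal[2]
    assert abs(orth0 - orth1) <= 0.05
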