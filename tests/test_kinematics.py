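"""Rigid registration, anatomic frames and joint-coordinate-system angles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stiflemech.errors import (
    DegenerateGeometryError,
    InputError,
    SingularConfigurationError,
)
from stiflemech.kinematics import (
    AnatomicalFrame,
    BoneLandmarks,
    JcsPose,
    MarkerTriad,
    Point3,
    RigidTransform,
    build_femoral_frame,
    build_tibial_frame,
    ccl_translation,
    compute_pose,
    fit_rigid,
    jcs_compose,
    jcs_decompose,
    transfer_landmarks,
)
from stiflemech.synthetic import make_specimen, render_condition

from conftest import axis_aligned_femur, axis_aligned_tibia

TRIAD = np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0], [5.0, 40.0, 10.0]])


def random_rigid(rng) -> RigidTransform:
    return RigidTransform(
        Rotation.random(random_state=rng).as_matrix(),
        rng.uniform(-50, 50, 3),
        "a",
        "b",
    )


class TestFitRigid:
    def test_identity(self):
        T = fit_rigid(TRIAD, TRIAD)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(T.translation, 0, atol=1e-12)
        assert T.rms_residual <= 1e-12

    def test_recovers_known_transform(self):
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        T = fit_rigid(TRIAD, TRIAD @ R.T + t)
        assert np.allclose(T.rotation, R, atol=1e-12)
        assert np.allclose(T.translation, t, atol=1e-10)
        assert T.rms_residual < 1e-10

    def test_proper_rotation_for_random_inputs(self, rng):
        for _ in range(50):
            src = rng.uniform(-60, 60, (rng.integers(3, 8), 3))
            if np.linalg.svd(src - src.mean(0), compute_uv=False)[1] < 1.0:
                continue
            tgt = rng.uniform(-60, 60, src.shape)
            T = fit_rigid(src, tgt)
            assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_translation_error_within_mc_bound(self, rng):
        # bound frozen from an independent Monte-Carlo oracle run at the
        # digitizer noise level (median error 0.29 mm for this geometry)
        errs = []
        for _ in range(300):
            T = random_rigid(rng)
            noisy = TRIAD @ T.rotation.T + T.translation + rng.normal(0, 0.23, (3, 3))
            fit = fit_rigid(TRIAD, noisy)
            errs.append(np.linalg.norm(fit.translation - T.translation))
        assert np.median(errs) < 0.35

    def test_collinear_source_rejected(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            fit_rigid(line, line)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InputError):
            fit_rigid(TRIAD, TRIAD[:2])


class TestTransferLandmarks:
    def test_identity_markers_relabel_frame(self, femur_landmarks):
        lm_ct = BoneLandmarks(
            role="femur",
            points={
                n: Point3(p.x, p.y, p.z, "ct_femur")
                for n, p in femur_landmarks.points.items()
            },
        )
        mk_ct = MarkerTriad.from_array(TRIAD, "ct_femur")
        mk_lab = MarkerTriad.from_array(TRIAD, "lab")
        out = transfer_landmarks(lm_ct, mk_ct, mk_lab)
        assert out.frame == "lab"
        for name, p in lm_ct.points.items():
            assert np.allclose(out[name].as_array(), p.as_array(), atol=1e-10)

    def test_matches_directly_transformed_landmarks(self, femur_landmarks, rng):
        lm_ct = BoneLandmarks(
            role="femur",
            points={
                n: Point3(p.x, p.y, p.z, "ct_femur")
                for n, p in femur_landmarks.points.items()
            },
        )
        mk_ct = MarkerTriad.from_array(TRIAD, "ct_femur")
        T = random_rigid(rng)
        mk_lab = MarkerTriad.from_array(T.apply(TRIAD), "lab")
        out = transfer_landmarks(lm_ct, mk_ct, mk_lab)
        for name, p in lm_ct.points.items():
            assert np.allclose(out[name].as_array(), T.apply(p.as_array()), atol=1e-9)


class TestAnatomicalFrames:
    def test_axis_aligned_femur(self, femur_landmarks):
        f = build_femoral_frame(femur_landmarks)
        assert np.allclose(f.origin.as_array(), 0, atol=1e-12)
        assert np.allclose(f.ml, [1, 0, 0])  # medial condyle at +x
        assert np.allclose(f.pd, [0, 0, 1])
        assert np.allclose(f.ap, [0, 1, 0])

    def test_axis_aligned_tibia(self, tibia_landmarks):
        f = build_tibial_frame(tibia_landmarks)
        assert np.allclose(f.ml, [1, 0, 0])
        assert np.allclose(f.pd, [0, 0, 1])
        assert np.allclose(f.ap, [0, 1, 0])

    @pytest.mark.parametrize("builder,make", [
        (build_femoral_frame, axis_aligned_femur),
        (build_tibial_frame, axis_aligned_tibia),
    ])
    def test_equivariance_under_rigid_motion(self, builder, make, rng):
        base = make("a")
        f0 = builder(base)
        for _ in range(20):
            T = random_rigid(rng)
            f1 = builder(base.transformed(T))
            assert np.allclose(f1.origin.as_array(), T.apply(f0.origin.as_array()), atol=1e-9)
            assert np.allclose(f1.axes, f0.axes @ T.rotation.T, atol=1e-9)

    def test_orthonormality_on_synthetic_specimen(self):
        spec = make_specimen(seed=9)
        for frame in (
            build_femoral_frame(spec.femur_landmarks),
            build_tibial_frame(spec.tibia_landmarks),
        ):
            assert np.max(np.abs(frame.axes @ frame.axes.T - np.eye(3))) < 1e-12

    def test_degenerate_condyles_rejected(self, femur_landmarks):
        pts = dict(femur_landmarks.points)
        pts["lateral_condyle_center"] = pts["medial_condyle_center"]
        with pytest.raises(DegenerateGeometryError):
            build_femoral_frame(BoneLandmarks(role="femur", points=pts))

    def test_head_on_condylar_line_rejected(self, femur_landmarks):
        pts = dict(femur_landmarks.points)
        pts["femoral_head_center"] = Point3(40.0, 0.0, 0.0, "lab")
        with pytest.raises(DegenerateGeometryError):
            build_femoral_frame(BoneLandmarks(role="femur", points=pts))


def frames_from_relative_rotation(M):
    femoral = AnatomicalFrame(role="femur", origin=Point3(0, 0, 0, "lab"), axes=np.eye(3))
    tibial = AnatomicalFrame(role="tibia", origin=Point3(0, 0, 0, "lab"), axes=M.T)
    return femoral, tibial


class TestJcs:
    def test_pure_flexion_about_e1(self):
        """A -41.5 deg rotation about the femoral ML axis is pure flexion:
        the included joint angle drops from 180 to 138.5 deg."""
        M = Rotation.from_euler("X", -41.5, degrees=True).as_matrix()
        fe, vv, ie = jcs_decompose(*frames_from_relative_rotation(M))
        assert fe == pytest.approx(138.5, abs=1e-10)
        assert vv == pytest.approx(0.0, abs=1e-10)
        assert ie == pytest.approx(0.0, abs=1e-10)

    def test_collinear_long_axes_give_180(self):
        T = jcs_compose(180.0, 0.0, 0.0)
        assert np.allclose(T.rotation, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("angles", [
        (138.5, 10.4, 13.8),  # intact, stance-phase angle
        (142.7, 5.3, -4.6),  # CCL-deficient, stance-phase angle
        (101.5, 2.8, 10.7),  # intact, high flexion
        (102.7, 2.4, -8.3),  # CCL-deficient, high flexion
    ])
    def test_compose_decompose_round_trip(self, angles):
        M = jcs_compose(*angles).rotation
        out = jcs_decompose(*frames_from_relative_rotation(M))
        assert np.allclose(out, angles, atol=1e-9)

    def test_round_trip_grid(self):
        for fe in np.linspace(95, 175, 9):
            for vv in np.linspace(-15, 15, 5):
                for ie in np.linspace(-20, 20, 5):
                    M = jcs_compose(fe, vv, ie).rotation
                    out = jcs_decompose(*frames_from_relative_rotation(M))
                    assert np.allclose(out, (fe, vv, ie), atol=1e-8)

    def test_gimbal_lock_raises(self):
        # tibial long axis pulled (almost) onto the femoral ML axis
        M = Rotation.from_euler("Y", 89.0, degrees=True).as_matrix()
        with pytest.raises(SingularConfigurationError) as exc:
            jcs_decompose(*frames_from_relative_rotation(M))
        assert exc.value.alignment > 0.99

    def test_compose_rejects_out_of_range_flexion(self):
        with pytest.raises(InputError):
            jcs_compose(0.0, 0.0, 0.0)
        with pytest.raises(InputError):
            jcs_compose(190.0, 0.0, 0.0)


class TestCclTranslation:
    def test_zero_for_coincident_points(self, tibia_landmarks):
        frame = build_tibial_frame(tibia_landmarks)
        p = Point3(3.0, 4.0, 5.0, "lab")
        assert ccl_translation(p, p, frame) == (0.0, 0.0, 0.0)

    def test_constructed_components(self, tibia_landmarks):
        frame = build_tibial_frame(tibia_landmarks)
        origin = Point3(0.0, 0.0, 0.0, "lab")
        v = 10.2 * frame.ap + 9.1 * frame.ml + 4.6 * (-frame.pd)
        insertion = Point3.from_array(v, "lab")
        t_cacr, t_ml, t_dp = ccl_translation(origin, insertion, frame)
        assert (t_cacr, t_ml, t_dp) == pytest.approx((10.2, 9.1, 4.6), abs=1e-12)

    def test_invariant_under_joint_rigid_motion(self, tibia_landmarks, rng):
        frame = build_tibial_frame(tibia_landmarks)
        origin = Point3(1.0, 2.0, 3.0, "lab")
        insertion = Point3(4.0, -1.0, 2.0, "lab")
        ref = ccl_translation(origin, insertion, frame)
        for _ in range(10):
            T = RigidTransform(
                Rotation.random(random_state=rng).as_matrix(),
                rng.uniform(-50, 50, 3),
                "lab",
                "lab",
            )
            out = ccl_translation(
                T.apply_point(origin), T.apply_point(insertion), frame.transformed(T)
            )
            assert np.allclose(out, ref, atol=1e-10)

    def test_frame_mismatch_rejected(self, tibia_landmarks):
        frame = build_tibial_frame(tibia_landmarks)
        with pytest.raises(InputError):
            ccl_translation(
                Point3(0, 0, 0, "ct_femur"), Point3(0, 0, 0, "lab"), frame
            )


class TestComputePose:
    @pytest.mark.parametrize("pose", [
        JcsPose(142.7, 5.3, -4.6, 25.1, 10.6, -2.5),  # CCL-deficient stance
        JcsPose(180.0, 0.0, 0.0, 0.0, 0.0, 0.0),  # identity fixture
    ])
    def test_zero_noise_recovery_is_exact(self, pose):
        spec = make_specimen(seed=21)
        fm, tm = render_condition(spec, pose, noise_sd=0.0, seed=4)
        out = compute_pose(
            spec.femur_landmarks, spec.tibia_landmarks,
            spec.femur_markers, fm, spec.tibia_markers, tm,
        )
        assert np.allclose(out.as_tuple(), pose.as_tuple(), atol=1e-9)

    def test_noisy_recovery_unbiased_and_noise_monotone(self, rng):
        spec = make_specimen(seed=22)
        pose = JcsPose(138.5, 10.4, 13.8, 10.2, 9.1, 4.6)

        def errors(noise_sd, n=60):
            errs = []
            for _ in range(n):
                fm, tm = render_condition(spec, pose, noise_sd=noise_sd, seed=rng)
                out = compute_pose(
                    spec.femur_landmarks, spec.tibia_landmarks,
                    spec.femur_markers, fm, spec.tibia_markers, tm,
                )
                errs.append(np.subtract(out.as_tuple(), pose.as_tuple()))
            return np.asarray(errs)

        lo, hi = errors(0.05), errors(0.4)
        # spread shrinks with the noise scale; bias stays near zero
        assert np.all(lo.std(axis=0) < hi.std(axis=0))
        assert np.all(np.abs(lo.mean(axis=0)) < 0.2)


class TestValidation:
    def test_marker_triad_rejects_collinear(self):
        with pytest.raises(DegenerateGeometryError):
            MarkerTriad.from_array(
                np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]), "lab"
            )

    def test_landmarks_require_all_names(self):
        with pytest.raises(InputError):
            BoneLandmarks(role="femur", points={"ccl_origin": Point3(0, 0, 0, "x")})

    def test_pose_range_checks(self):
        with pytest.raises(InputError):
            JcsPose(0.0, 0, 0, 0, 0, 0)
        with pytest.raises(InputError):
            JcsPose(float("nan"), 0, 0, 0, 0, 0)

    def test_rigid_transform_rejects_reflection(self):
        with pytest.raises(InputError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3), "a", "b")
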