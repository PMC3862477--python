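"""Rigid-body kinematics of the femorotibial joint.

This module reconstructs the static 3-D pose of the tibia relative to the
femur from digitized inputs and decomposes it into clinically meaningful
alignment numbers:

* three rotations in the Grood-Suntay joint coordinate system (JCS), using
  body-fixed axes in the order flexion/extension, adduction/abduction
  (varus/valgus), internal/external tibial rotation;
* three translations, measured as the vector from the femoral origin of the
  cranial cruciate ligament (CCL) to its tibial insertion and resolved in an
  orthogonal anatomic coordinate system fixed to the tibia.

Conventions
-----------
All public angles are in degrees and all lengths in millimetres.  Anatomic
frames use the right-handed axis triple (ML, AP, PD) = (medial, cranial,
proximal); left limbs are mirrored to this canonical handedness at file
ingest (see :mod:`stiflemech.io`), so "medial", "varus" and "internal" carry
a single sign convention internally.

Flexion/extension is reported as the *included joint angle* measured between
the long axes of femur and tibia: collinear bones give 180 deg (full
extension) and smaller values mean more flexion, matching goniometric
practice.  The raw Grood-Suntay flexion rotation has magnitude ``180 - reported``.
Positive varus/valgus is varus, positive internal/external is external
tibial rotation, and positive translations are cranial, medial and
distracted respectively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, InputError, SingularConfigurationError

__all__ = [
    "Point3",
    "MarkerTriad",
    "BoneLandmarks",
    "RigidTransform",
    "AnatomicalFrame",
    "JcsPose",
    "FEMUR_LANDMARK_NAMES",
    "TIBIA_LANDMARK_NAMES",
    "fit_rigid",
    "transfer_landmarks",
    "build_femoral_frame",
    "build_tibial_frame",
    "jcs_decompose",
    "jcs_compose",
    "ccl_translation",
    "compute_pose",
]

#: minimum triangle altitude (mm) below which a marker triad is degenerate
COLLINEARITY_TOL_MM = 1e-6

#: |e1 . e3| above which the JCS decomposition refuses to report angles
GIMBAL_TOL = 0.99

#: orthonormality tolerance for rotation matrices and frame axes
ORTHO_TOL = 1e-9

FEMUR_LANDMARK_NAMES = (
    "medial_condyle_center",
    "lateral_condyle_center",
    "femoral_head_center",
    "ccl_origin",
)
TIBIA_LANDMARK_NAMES = (
    "medial_condyle_edge",
    "lateral_condyle_edge",
    "distal_tibia_center",
    "ccl_insertion",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Point3:
    """A 3-D coordinate in millimetres tagged with the reference frame it is
    expressed in (e.g. ``"ct_femur"``, ``"lab"``)."""

    x: float
    y: float
    z: float
    frame: str

    def __post_init__(self):
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise InputError(f"non-finite coordinate in Point3: {self!r}")
        if not self.frame:
            raise InputError("Point3 requires a non-empty frame label")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a, frame: str) -> "Point3":
        a = np.asarray(a, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]), frame)


def _triangle_min_altitude(pts: np.ndarray) -> float:
    """Smallest altitude of the triangle spanned by three points (0 if the
    points are collinear or coincident)."""
    a, b, c = pts
    sides = [np.linalg.norm(b - a), np.linalg.norm(c - b), np.linalg.norm(a - c)]
    longest = max(sides)
    if longest == 0.0:
        return 0.0
    area2 = np.linalg.norm(np.cross(b - a, c - a))  # twice the triangle area
    return area2 / longest


@dataclass(frozen=True)
class MarkerTriad:
    """Three non-collinear digitized marker points (nylon screws) on one bone,
    all expressed in the same frame."""

    p1: Point3
    p2: Point3
    p3: Point3

    def __post_init__(self):
        frames = {self.p1.frame, self.p2.frame, self.p3.frame}
        if len(frames) != 1:
            raise InputError(f"marker triad mixes frames: {sorted(frames)}")
        if _triangle_min_altitude(self.as_array()) <= COLLINEARITY_TOL_MM:
            raise DegenerateGeometryError(
                "marker triad is collinear (or nearly so); cannot define a pose"
            )

    @property
    def frame(self) -> str:
        return self.p1.frame

    def as_array(self) -> np.ndarray:
        return np.stack([p.as_array() for p in (self.p1, self.p2, self.p3)])

    @classmethod
    def from_array(cls, a, frame: str) -> "MarkerTriad":
        a = np.asarray(a, dtype=float)
        if a.shape != (3, 3):
            raise InputError(f"marker triad needs shape (3, 3), got {a.shape}")
        return cls(*(Point3.from_array(row, frame) for row in a))


@dataclass(frozen=True)
class BoneLandmarks:
    """Named anatomical landmark points of one bone, all in one frame.

    ``role`` is ``"femur"`` (medial/lateral condyle centers, femoral head
    center, CCL origin) or ``"tibia"`` (medial/lateral condyle outer edges,
    distal tibia center, CCL insertion).
    """

    role: str
    points: Mapping[str, Point3]

    def __post_init__(self):
        required = {"femur": FEMUR_LANDMARK_NAMES, "tibia": TIBIA_LANDMARK_NAMES}
        if self.role not in required:
            raise InputError(f"unknown bone role {self.role!r}")
        missing = [n for n in required[self.role] if n not in self.points]
        if missing:
            raise InputError(f"{self.role} landmarks missing {missing}")
        frames = {p.frame for p in self.points.values()}
        if len(frames) != 1:
            raise InputError(f"landmarks mix frames: {sorted(frames)}")
        object.__setattr__(self, "points", dict(self.points))

    @property
    def frame(self) -> str:
        return next(iter(self.points.values())).frame

    def __getitem__(self, name: str) -> Point3:
        return self.points[name]

    def transformed(self, transform: "RigidTransform") -> "BoneLandmarks":
        """All landmarks mapped through ``transform`` (frames relabeled)."""
        return BoneLandmarks(
            role=self.role,
            points={n: transform.apply_point(p) for n, p in self.points.items()},
        )


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` mapping coordinates from
    ``from_frame`` to ``to_frame``.  ``rms_residual`` is populated by
    :func:`fit_rigid` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: str
    to_frame: str
    rms_residual: float = 0.0

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InputError(f"rotation must be 3x3, got {R.shape}")
        if np.max(np.abs(R.T @ R - np.eye(3))) > ORTHO_TOL:
            raise InputError("rotation matrix is not orthonormal within 1e-9")
        if abs(np.linalg.det(R) - 1.0) > ORTHO_TOL:
            raise InputError("rotation matrix is not proper (det != +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls, from_frame: str, to_frame: str) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), from_frame, to_frame)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) array (or a single 3-vector)."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_point(self, p: Point3) -> Point3:
        if p.frame != self.from_frame:
            raise InputError(
                f"point is in frame {p.frame!r}, transform maps from "
                f"{self.from_frame!r}"
            )
        return Point3.from_array(self.apply(p.as_array()), self.to_frame)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation, self.to_frame, self.from_frame)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """The transform ``self o first`` (apply ``first``, then ``self``)."""
        if first.to_frame != self.from_frame:
            raise InputError(
                f"cannot chain {first.to_frame!r} -> {self.from_frame!r}"
            )
        return RigidTransform(
            self.rotation @ first.rotation,
            self.rotation @ first.translation + self.translation,
            first.from_frame,
            self.to_frame,
        )


@dataclass(frozen=True)
class AnatomicalFrame:
    """An orthogonal anatomic coordinate system fixed to one bone.

    ``axes`` is a 3x3 array whose rows are the unit ML (medial), AP (cranial)
    and PD (proximal) directions expressed in the reference frame the input
    landmarks were given in.
    """

    role: str
    origin: Point3
    axes: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.axes, dtype=float)
        if A.shape != (3, 3):
            raise InputError(f"axes must be 3x3, got {A.shape}")
        if np.max(np.abs(A @ A.T - np.eye(3))) > ORTHO_TOL:
            raise InputError("frame axes are not orthonormal within 1e-9")
        if np.linalg.det(A) < 0:
            raise InputError("frame axes are left-handed")
        object.__setattr__(self, "axes", A)

    @property
    def frame(self) -> str:
        return self.origin.frame

    @property
    def ml(self) -> np.ndarray:  # medial
        return self.axes[0]

    @property
    def ap(self) -> np.ndarray:  # cranial
        return self.axes[1]

    @property
    def pd(self) -> np.ndarray:  # proximal
        return self.axes[2]

    def basis(self) -> np.ndarray:
        """Rotation matrix with the frame axes as *columns* (frame -> lab)."""
        return self.axes.T

    def transformed(self, transform: RigidTransform) -> "AnatomicalFrame":
        return AnatomicalFrame(
            role=self.role,
            origin=transform.apply_point(self.origin),
            axes=self.axes @ transform.rotation.T,
        )


@dataclass(frozen=True)
class JcsPose:
    """The six alignment numbers of one loading condition.

    flexion_extension
        included stifle joint angle, deg; larger = more extended, 180 = bones
        collinear.
    varus_valgus
        deg, positive = varus.
    internal_external
        deg, positive = external tibial rotation.
    t_cacr, t_ml, t_dp
        CCL origin-to-insertion translation components, mm; positive =
        cranial, medial and distracted respectively.
    """

    flexion_extension: float
    varus_valgus: float
    internal_external: float
    t_cacr: float
    t_ml: float
    t_dp: float

    def __post_init__(self):
        vals = (
            self.flexion_extension,
            self.varus_valgus,
            self.internal_external,
            self.t_cacr,
            self.t_ml,
            self.t_dp,
        )
        if not all(math.isfinite(v) for v in vals):
            raise InputError(f"non-finite pose component in {self!r}")
        if not (0.0 < self.flexion_extension <= 180.0):
            raise InputError(
                f"flexion_extension must lie in (0, 180], got "
                f"{self.flexion_extension}"
            )

    def as_tuple(self) -> tuple:
        return (
            self.flexion_extension,
            self.varus_valgus,
            self.internal_external,
            self.t_cacr,
            self.t_ml,
            self.t_dp,
        )

    FIELDS = (
        "flexion_extension",
        "varus_valgus",
        "internal_external",
        "t_cacr",
        "t_ml",
        "t_dp",
    )


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def _points_to_array(points, what: str) -> tuple[np.ndarray, str | None]:
    if isinstance(points, np.ndarray):
        a = np.asarray(points, dtype=float)
        frame = None
    else:
        points = list(points)
        if points and isinstance(points[0], Point3):
            frames = {p.frame for p in points}
            if len(frames) != 1:
                raise InputError(f"{what} points mix frames: {sorted(frames)}")
            frame = points[0].frame
            a = np.stack([p.as_array() for p in points])
        else:
            a = np.asarray(points, dtype=float)
            frame = None
    if a.ndim != 2 or a.shape[1] != 3:
        raise InputError(f"{what} must be an (n, 3) point set, got {a.shape}")
    return a, frame


def fit_rigid(source, target) -> RigidTransform:
    """Least-squares rigid registration (Kabsch) of matched point sets.

    Finds the proper rigid transform minimizing ``sum ||R s_i + t - t_i||^2``
    over rotations with det +1 (no scaling, no reflection).  ``source`` and
    ``target`` are matched by index and may be lists of :class:`Point3` or
    (n, 3) arrays with n >= 3.  The RMS point residual (mm) is stored on the
    returned transform.

    Raises
    ------
    InputError
        on mismatched lengths or fewer than 3 pairs.
    DegenerateGeometryError
        when the source points are (near-)collinear, which leaves the
        rotation about the point line unconstrained.
    """
    src, src_frame = _points_to_array(source, "source")
    tgt, tgt_frame = _points_to_array(target, "target")
    if src.shape[0] != tgt.shape[0]:
        raise InputError(
            f"source has {src.shape[0]} points but target has {tgt.shape[0]}"
        )
    if src.shape[0] < 3:
        raise InputError("rigid registration needs at least 3 point pairs")

    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)

    # collinearity check: the second principal extent must be non-negligible
    svals = np.linalg.svd(src_c, compute_uv=False)
    if svals[1] <= COLLINEARITY_TOL_MM:
        raise DegenerateGeometryError(
            "source points are collinear; rotation is not identifiable"
        )

    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])  # reflection guard: flip smallest singular vector
    R = Vt.T @ D @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    resid = tgt - (src @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(
        rotation=R,
        translation=t,
        from_frame=src_frame or "source",
        to_frame=tgt_frame or "target",
        rms_residual=rms,
    )


def transfer_landmarks(
    landmarks_ct: BoneLandmarks,
    markers_ct: MarkerTriad,
    markers_lab: MarkerTriad,
) -> BoneLandmarks:
    """Express CT-frame landmarks in the lab frame of one loading condition.

    The nylon-screw marker triad is digitized both in the CT/bone frame and
    in the lab during loading; the rigid transform fitted between the two
    digitizations carries every landmark into the lab frame.
    """
    if landmarks_ct.frame != markers_ct.frame:
        raise InputError(
            f"landmarks are in {landmarks_ct.frame!r} but CT markers in "
            f"{markers_ct.frame!r}"
        )
    T = fit_rigid(
        [markers_ct.p1, markers_ct.p2, markers_ct.p3],
        [markers_lab.p1, markers_lab.p2, markers_lab.p3],
    )
    return landmarks_ct.transformed(T)


# ---------------------------------------------------------------------------
# anatomic frames
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n <= COLLINEARITY_TOL_MM:
        raise DegenerateGeometryError(f"{what} is degenerate (zero length)")
    return v / n


def build_femoral_frame(landmarks: BoneLandmarks) -> AnatomicalFrame:
    """Anatomic frame of the femur.

    Origin at the midpoint of the condyle centers; ML axis along the
    transcondylar line (pointing medial); PD axis is the component of the
    origin-to-femoral-head direction orthogonal to ML (pointing proximal);
    AP completes the right-handed triple (pointing cranial).
    """
    if landmarks.role != "femur":
        raise InputError(f"expected femur landmarks, got {landmarks.role!r}")
    med = landmarks["medial_condyle_center"].as_array()
    lat = landmarks["lateral_condyle_center"].as_array()
    head = landmarks["femoral_head_center"].as_array()
    origin = 0.5 * (med + lat)
    ml = _unit(med - lat, "femoral transcondylar axis")
    pd_raw = head - origin
    pd = pd_raw - (pd_raw @ ml) * ml
    pd = _unit(pd, "femoral long axis (head center on the condylar line?)")
    ap = np.cross(pd, ml)
    return AnatomicalFrame(
        role="femur",
        origin=Point3.from_array(origin, landmarks.frame),
        axes=np.stack([ml, ap, pd]),
    )


def build_tibial_frame(landmarks: BoneLandmarks) -> AnatomicalFrame:
    """Anatomic frame of the tibia.

    Origin at the midpoint of the condyle outer edges; PD axis from the
    distal tibia center toward that midpoint (pointing proximal); ML axis is
    the component of the inter-edge direction orthogonal to PD (pointing
    medial); AP completes the right-handed triple.  PD is taken as the
    primary axis because it is the body-fixed tibial axis of the joint
    coordinate system.
    """
    if landmarks.role != "tibia":
        raise InputError(f"expected tibia landmarks, got {landmarks.role!r}")
    med = landmarks["medial_condyle_edge"].as_array()
    lat = landmarks["lateral_condyle_edge"].as_array()
    distal = landmarks["distal_tibia_center"].as_array()
    origin = 0.5 * (med + lat)
    pd = _unit(origin - distal, "tibial long axis")
    ml_raw = med - lat
    ml = ml_raw - (ml_raw @ pd) * pd
    ml = _unit(ml, "tibial ML axis (edges along the long axis?)")
    ap = np.cross(pd, ml)
    return AnatomicalFrame(
        role="tibia",
        origin=Point3.from_array(origin, landmarks.frame),
        axes=np.stack([ml, ap, pd]),
    )


# ---------------------------------------------------------------------------
# joint coordinate system
# ---------------------------------------------------------------------------


def _relative_rotation(femoral: AnatomicalFrame, tibial: AnatomicalFrame) -> np.ndarray:
    if femoral.frame != tibial.frame:
        raise InputError(
            f"frames live in different reference frames: {femoral.frame!r} vs "
            f"{tibial.frame!r}"
        )
    # maps tibia-frame coordinates into femur-frame coordinates
    return femoral.axes @ tibial.axes.T


def jcs_decompose(
    femoral: AnatomicalFrame, tibial: AnatomicalFrame
) -> tuple[float, float, float]:
    """Grood-Suntay rotations of the tibia relative to the femur.

    The body-fixed axes are e1 = femoral ML, e3 = tibial PD, with the
    floating axis e2 = e3 x e1; equivalently an intrinsic X-Y-Z Euler
    decomposition of the relative rotation in (ML, AP, PD) coordinates.
    Returns ``(flexion_extension, varus_valgus, internal_external)`` in
    degrees with the sign conventions of :class:`JcsPose`.

    Raises
    ------
    SingularConfigurationError
        when ``|e1 . e3| > 0.99`` (gimbal lock: femoral ML nearly parallel to
        the tibial long axis), reporting the offending alignment.
    """
    M = _relative_rotation(femoral, tibial)
    alignment = abs(M[0, 2])  # e1 . e3
    if alignment > GIMBAL_TOL:
        raise SingularConfigurationError(alignment)
    alpha, beta, gamma = Rotation.from_matrix(M).as_euler("XYZ", degrees=True)
    # flexing the stifle tilts the tibial long axis cranially, i.e. a negative
    # rotation about the medial axis, so the included joint angle is 180 + alpha
    return 180.0 + alpha, -beta, gamma


def jcs_compose(
    flexion_extension: float,
    varus_valgus: float,
    internal_external: float,
) -> RigidTransform:
    """Relative orientation of the tibial anatomic frame in femoral anatomic
    coordinates for the given JCS angles (inverse of :func:`jcs_decompose`).

    The returned transform is a pure rotation mapping tibia-frame coordinates
    to femur-frame coordinates; ``flexion_extension`` must lie in (0, 180].
    """
    if not (0.0 < flexion_extension <= 180.0):
        raise InputError(
            f"flexion_extension must lie in (0, 180], got {flexion_extension}"
        )
    R = Rotation.from_euler(
        "XYZ",
        [flexion_extension - 180.0, -varus_valgus, internal_external],
        degrees=True,
    ).as_matrix()
    return RigidTransform(R, np.zeros(3), "tibia_anatomic", "femur_anatomic")


def ccl_translation(
    ccl_origin_lab: Point3,
    ccl_insertion_lab: Point3,
    tibial: AnatomicalFrame,
) -> tuple[float, float, float]:
    """Tibial translation relative to the femur, measured from CCL origin to
    insertion and resolved in the tibial anatomic frame.

    Returns ``(t_cacr, t_ml, t_dp)`` in mm: positive cranial, positive
    medial, positive distracted (the distraction direction is the *distal*
    direction, -PD).
    """
    if ccl_origin_lab.frame != ccl_insertion_lab.frame:
        raise InputError(
            f"CCL points live in different frames: {ccl_origin_lab.frame!r} vs "
            f"{ccl_insertion_lab.frame!r}"
        )
    if ccl_origin_lab.frame != tibial.frame:
        raise InputError(
            f"CCL points in {ccl_origin_lab.frame!r} but tibial frame in "
            f"{tibial.frame!r}"
        )
    v = ccl_insertion_lab.as_array() - ccl_origin_lab.as_array()
    return float(v @ tibial.ap), float(v @ tibial.ml), float(-(v @ tibial.pd))


def compute_pose(
    femur_landmarks_ct: BoneLandmarks,
    tibia_landmarks_ct: BoneLandmarks,
    femur_markers_ct: MarkerTriad,
    femur_markers_lab: MarkerTriad,
    tibia_markers_ct: MarkerTriad,
    tibia_markers_lab: MarkerTriad,
) -> JcsPose:
    """End-to-end pose reconstruction for one loading condition.

    CT-frame landmarks of both bones are carried into the lab frame through
    the marker-triad registrations, anatomic frames are built there, and the
    rotations and CCL translations are extracted.  Deterministic given its
    inputs.
    """
    femur_lab = transfer_landmarks(femur_landmarks_ct, femur_markers_ct, femur_markers_lab)
    tibia_lab = transfer_landmarks(tibia_landmarks_ct, tibia_markers_ct, tibia_markers_lab)
    femoral_frame = build_femoral_frame(femur_lab)
    tibial_frame = build_tibial_frame(tibia_lab)
    fe, vv, ie = jcs_decompose(femoral_frame, tibial_frame)
    if 180.0 < fe < 180.0 + 1e-6:  # numerical overshoot at exact extension
        fe = 180.0
    t_cacr, t_ml, t_dp = ccl_translation(
        femur_lab["ccl_origin"], tibia_lab["ccl_insertion"], tibial_frame
    )
    return JcsPose(fe, vv, ie, t_cacr, t_ml, t_dp)
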