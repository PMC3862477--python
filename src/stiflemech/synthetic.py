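"""Synthetic cadaver-specimen generator.

No public dataset of digitized stifle landmarks and femorotibial pressure
maps exists, so this module generates complete synthetic specimens with the
statistical structure of the ex vivo study design: an idealized canine
stifle geometry, marker triads digitized in per-bone CT frames and in a lab
frame per loading condition (with digitizer noise), and per-compartment
sensel grids carrying contact patches of controllable location, area and
peak pressure.

The generator is the exact inverse of the analysis pipeline: a ground-truth
:class:`~stiflemech.kinematics.JcsPose` is turned into lab marker
coordinates by composing the joint coordinate system rotation and placing
the tibia so that the CCL origin-to-insertion vector carries the requested
translations, and a patch of requested fractional craniocaudal position,
peak pressure and contact area is rasterized onto the sensel grid.  With
zero noise the pipeline therefore recovers the ground truth exactly; with
realistic noise the recovery error is governed by the 0.23 mm digitizer
accuracy (modelled as an isotropic per-coordinate Gaussian with sd
0.23 mm).

The default cohort configuration encodes the study conditions: n = 8
specimens, four loading conditions (intact/transected CCL at the ~135 deg
stance-phase angle and the ~90 deg high-flexion angle), with per-condition
means and between-specimen standard deviations for the pose components and
the per-compartment contact-patch parameters taken from the measured
condition summaries of the modelled experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from .contact import (
    DEFAULT_SATURATION_MPA,
    DEFAULT_SENSITIVITY_MPA,
    CondyleMargins,
    PressureMap,
)
from .errors import InfeasiblePatchError, InputError
from .kinematics import (
    BoneLandmarks,
    JcsPose,
    MarkerTriad,
    Point3,
    RigidTransform,
    build_femoral_frame,
    build_tibial_frame,
    jcs_compose,
)

__all__ = [
    "SpecimenTemplate",
    "GridSpec",
    "PatchParams",
    "PatchEffect",
    "ConditionEffect",
    "SyntheticSpecimen",
    "ConditionData",
    "SyntheticCohort",
    "DIGITIZER_NOISE_SD_MM",
    "CONDITIONS",
    "default_condition_effects",
    "make_specimen",
    "render_condition",
    "render_pressure_map",
    "make_cohort",
]

#: digitizing-arm accuracy, read as a 1-sd isotropic per-coordinate noise (mm)
DIGITIZER_NOISE_SD_MM = 0.23

#: the four loading conditions in acquisition order: (flexion label, CCL status)
CONDITIONS = (
    ("90", "intact"),
    ("135", "intact"),
    ("135", "transected"),
    ("90", "transected"),
)


# ---------------------------------------------------------------------------
# geometry template
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpecimenTemplate:
    """Idealized canine stifle geometry (mm / deg), sized for a ~30 kg dog.

    Anatomic coordinates are (medial, cranial, proximal); the femoral
    template is expressed around the femoral frame origin (transcondylar
    midpoint) and the tibial template around the tibial frame origin
    (inter-edge midpoint).
    """

    femoral_condyle_spacing: float = 25.0
    femur_length: float = 200.0
    tibia_length: float = 210.0
    tibial_condyle_span: float = 30.0
    tibial_plateau_angle_deg: float = 23.0
    ccl_origin_offset: tuple = (-3.0, -6.0, 1.0)
    ccl_insertion_offset: tuple = (1.0, 7.0, -4.0)
    marker_jitter_mm: float = 2.0

    def __post_init__(self):
        for name in (
            "femoral_condyle_spacing",
            "femur_length",
            "tibia_length",
            "tibial_condyle_span",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"template {name} must be positive")


@dataclass(frozen=True)
class SyntheticSpecimen:
    """CT-frame landmark and marker geometry of one synthetic specimen."""

    specimen_id: str
    side: str
    femur_landmarks: BoneLandmarks
    tibia_landmarks: BoneLandmarks
    femur_markers: MarkerTriad
    tibia_markers: MarkerTriad

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise InputError(f"side must be left|right, got {self.side!r}")


def _random_rigid(rng: np.random.Generator, frame_from: str, frame_to: str) -> RigidTransform:
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-50.0, 50.0, size=3)
    return RigidTransform(R, t, frame_from, frame_to)


def make_specimen(
    template: SpecimenTemplate = SpecimenTemplate(),
    seed: int | np.random.Generator = 0,
    specimen_id: str = "S1",
    side: str = "right",
) -> SyntheticSpecimen:
    """Generate one specimen's CT-frame landmarks and marker triads.

    The anatomy is laid out in canonical anatomic coordinates and then
    scrambled by an arbitrary rigid motion per bone, so the CT frames bear no
    special relationship to the anatomic frames (as for a real scan).
    Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = template.femoral_condyle_spacing / 2.0
    jit = template.marker_jitter_mm

    # femur in its anatomic coordinates
    femur_pts = {
        "medial_condyle_center": np.array([s, 0.0, 0.0]),
        "lateral_condyle_center": np.array([-s, 0.0, 0.0]),
        "femoral_head_center": np.array([0.0, 0.0, template.femur_length])
        + np.concatenate([rng.uniform(-3.0, 3.0, 2), [0.0]]),
        "ccl_origin": np.asarray(template.ccl_origin_offset, dtype=float),
    }
    femur_markers = np.array(
        [[10.0, 8.0, 60.0], [-12.0, 5.0, 110.0], [4.0, -10.0, 160.0]]
    ) + rng.uniform(-jit, jit, size=(3, 3))

    # tibia in its anatomic coordinates; the caudally sloped plateau lowers
    # the cranial intercondylar area, so the CCL insertion drops by tan(TPA)
    # times its cranial offset
    half_span = template.tibial_condyle_span / 2.0
    insertion = np.asarray(template.ccl_insertion_offset, dtype=float).copy()
    insertion[2] -= math.tan(math.radians(template.tibial_plateau_angle_deg)) * insertion[1]
    tibia_pts = {
        "medial_condyle_edge": np.array([half_span, 0.0, 0.0]),
        "lateral_condyle_edge": np.array([-half_span, 0.0, 0.0]),
        "distal_tibia_center": np.array([0.0, 0.0, -template.tibia_length])
        + np.concatenate([rng.uniform(-3.0, 3.0, 2), [0.0]]),
        "ccl_insertion": insertion,
    }
    tibia_markers = np.array(
        [[8.0, 6.0, -50.0], [-10.0, 3.0, -100.0], [5.0, -8.0, -150.0]]
    ) + rng.uniform(-jit, jit, size=(3, 3))

    T_f = _random_rigid(rng, "femur_canonical", "ct_femur")
    T_t = _random_rigid(rng, "tibia_canonical", "ct_tibia")

    femur_landmarks = BoneLandmarks(
        role="femur",
        points={n: Point3.from_array(T_f.apply(p), "ct_femur") for n, p in femur_pts.items()},
    )
    tibia_landmarks = BoneLandmarks(
        role="tibia",
        points={n: Point3.from_array(T_t.apply(p), "ct_tibia") for n, p in tibia_pts.items()},
    )
    return SyntheticSpecimen(
        specimen_id=specimen_id,
        side=side,
        femur_landmarks=femur_landmarks,
        tibia_landmarks=tibia_landmarks,
        femur_markers=MarkerTriad.from_array(T_f.apply(femur_markers), "ct_femur"),
        tibia_markers=MarkerTriad.from_array(T_t.apply(tibia_markers), "ct_tibia"),
    )


# ---------------------------------------------------------------------------
# lab-frame rendering of a loading condition
# ---------------------------------------------------------------------------


def render_condition(
    specimen: SyntheticSpecimen,
    pose: JcsPose,
    noise_sd: float = DIGITIZER_NOISE_SD_MM,
    seed: int | np.random.Generator = 0,
) -> tuple[MarkerTriad, MarkerTriad]:
    """Lab-frame marker triads realizing a ground-truth pose.

    The femur is placed in the lab at an arbitrary rigid pose; the tibia is
    then placed so that (a) the tibial anatomic frame relates to the femoral
    one by the requested JCS rotations and (b) the CCL origin-to-insertion
    vector carries the requested translations.  Marker coordinates are
    perturbed by isotropic Gaussian digitizer noise (sd ``noise_sd`` mm per
    coordinate; 0 disables noise).

    Returns ``(femur_markers_lab, tibia_markers_lab)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    femoral = build_femoral_frame(specimen.femur_landmarks)
    tibial = build_tibial_frame(specimen.tibia_landmarks)

    T_f = _random_rigid(rng, "ct_femur", "lab")  # femur CT -> lab
    Q_f_lab = T_f.rotation @ femoral.basis()

    M = jcs_compose(
        pose.flexion_extension, pose.varus_valgus, pose.internal_external
    ).rotation
    Q_t_lab = Q_f_lab @ M
    R_t = Q_t_lab @ tibial.basis().T  # tibia CT -> lab rotation

    origin_lab = T_f.apply(specimen.femur_landmarks["ccl_origin"].as_array())
    # translation components in tibial-frame (ML, AP, PD) coordinates;
    # positive distraction is the distal (-PD) direction
    v_local = np.array([pose.t_ml, pose.t_cacr, -pose.t_dp])
    insertion_lab = origin_lab + Q_t_lab @ v_local
    insertion_ct = specimen.tibia_landmarks["ccl_insertion"].as_array()
    t_t = insertion_lab - R_t @ insertion_ct
    T_t = RigidTransform(R_t, t_t, "ct_tibia", "lab")

    fm = T_f.apply(specimen.femur_markers.as_array())
    tm = T_t.apply(specimen.tibia_markers.as_array())
    if noise_sd > 0:
        fm = fm + rng.normal(0.0, noise_sd, size=fm.shape)
        tm = tm + rng.normal(0.0, noise_sd, size=tm.shape)
    return MarkerTriad.from_array(fm, "lab"), MarkerTriad.from_array(tm, "lab")


# ---------------------------------------------------------------------------
# pressure-map rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Sensel grid geometry.  The default 26 x 10 grid tiles the 30.9 mm x
    12.0 mm sensing area (row pitch 30.9/26 mm, column pitch 1.2 mm)."""

    n_rows: int = 26
    n_cols: int = 10
    row_pitch: float = 30.9 / 26
    col_pitch: float = 1.2
    saturation: float = DEFAULT_SATURATION_MPA
    sensitivity: float = DEFAULT_SENSITIVITY_MPA

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise InputError("grid must have at least one row and column")
        if self.row_pitch <= 0 or self.col_pitch <= 0:
            raise InputError("sensel pitches must be positive")

    @property
    def sensel_area(self) -> float:
        return self.row_pitch * self.col_pitch

    @property
    def total_area(self) -> float:
        return self.n_rows * self.n_cols * self.sensel_area


#: super-Gaussian shape exponent: flattens the mound so the induced
#: mean/peak contact-pressure ratio (~0.4) matches femorotibial contact
#: measurements (a plain Gaussian, k = 1, would give ~0.17)
SHAPE_EXPONENT = 2.5

#: craniocaudal length scale of the peak mound (mm): local high-pressure
#: focus of femoral-condyle contact
MOUND_SIGMA_MM = 2.2

#: mound width / length anisotropy
MOUND_ASPECT = 0.8

#: background amplitude relative to the peak; must stay < 1 so the global
#: pressure maximum is always the mound center
BACKGROUND_LEVEL = 0.8

#: between-specimen sd of the background amplitude ratio (contact-field
#: shape heterogeneity beyond the three tracked patch parameters)
BACKGROUND_LEVEL_SD = 0.12

#: truncation bounds keeping the background below the peak and above the
#: mound shoulders
BACKGROUND_LEVEL_BOUNDS = (0.5, 0.95)

#: cranial offset of the load-bearing background centroid relative to the
#: peak-pressure focus (fraction of condyle length): femorotibial load is
#: carried slightly cranial of the pressure peak through the menisci
BACKGROUND_SKEW = 0.04

#: between-specimen sd of the background-centroid position (fraction of
#: condyle length), independent of the peak-focus wander
BACKGROUND_CENTER_JITTER_SD = 0.04

#: mediolateral length scale of the background (mm); condylar contact covers
#: most, but not all, of the 12 mm sensing-strip width
BACKGROUND_WIDTH_SIGMA_MM = 2.6


#: default digitized condyle margins on the 26-row grid (fractional rows)
DEFAULT_MARGINS = CondyleMargins(caudal_row=1.5, cranial_row=24.5)


def _bisect_scale(n_contact, target_n: float, area: float, thr: float) -> float:
    """Smallest length scale whose in-contact sensel count best matches the
    target (``n_contact`` is a monotone step function of the scale)."""
    lo, hi = 1e-3, 1.0
    while n_contact(hi) < target_n:
        hi *= 2.0
        if hi > 1e4:
            raise InfeasiblePatchError(
                f"cannot reach {area:.1f} mm^2 at threshold {thr}"
            )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if n_contact(mid) < target_n:
            lo = mid
        else:
            hi = mid
    # hi is the smallest scale reaching >= target, lo the largest below;
    # return whichever sensel count lands closer to the target
    return hi if abs(n_contact(hi) - target_n) <= abs(target_n - n_contact(lo)) else lo


@dataclass(frozen=True)
class PatchParams:
    """Ground-truth contact-patch parameters for one compartment map.

    ``center_fraction`` positions the pressure *peak* along the condyle
    (0 = caudal margin).  ``background_fraction`` positions the broad
    load-bearing background of the patch; it defaults to the peak position,
    but a cohort generator will typically pin it at the condition mean so
    that specimen-to-specimen peak wander (local cartilage/meniscus
    topography) rides on a stable whole-joint load distribution.
    """

    center_fraction: float  # craniocaudal peak position, 0 = caudal margin
    peak_mpa: float
    area_mm2: float
    background_fraction: float | None = None
    background_level: float = BACKGROUND_LEVEL

    def __post_init__(self):
        if not (0.0 <= self.center_fraction <= 1.0):
            raise InputError(f"center_fraction {self.center_fraction} outside [0, 1]")
        if self.background_fraction is not None and not (
            0.0 <= self.background_fraction <= 1.0
        ):
            raise InputError(
                f"background_fraction {self.background_fraction} outside [0, 1]"
            )
        if self.peak_mpa < 0:
            raise InputError("peak pressure must be >= 0")
        if self.area_mm2 < 0:
            raise InputError("target area must be >= 0")
        if not (0.0 <= self.background_level < 1.0):
            raise InputError(
                f"background_level {self.background_level} outside [0, 1)"
            )


def _mound(
    grid: GridSpec,
    r0: float,
    c0: float,
    sigma_len: float,
    sigma_width: float,
    peak: float,
    exponent: float,
) -> np.ndarray:
    rows = (np.arange(grid.n_rows, dtype=float) - r0) * grid.row_pitch
    cols = (np.arange(grid.n_cols, dtype=float) - c0) * grid.col_pitch
    q = (rows[:, None] ** 2) / (2.0 * sigma_len**2) + (cols[None, :] ** 2) / (
        2.0 * sigma_width**2
    )
    return peak * np.exp(-np.power(q, exponent))



def _field(
    grid: GridSpec,
    sigma_bg: float,
    r_peak: float,
    r_bg: float,
    c0: float,
    peak: float,
    bg_level: float,
) -> np.ndarray:
    """Two-component pressure field: broad background + peak mound (max)."""
    mound = _mound(
        grid, r_peak, c0, MOUND_SIGMA_MM, MOUND_ASPECT * MOUND_SIGMA_MM,
        peak, SHAPE_EXPONENT,
    )
    if sigma_bg <= 0.0 or bg_level <= 0.0:
        return mound
    bg = _mound(
        grid, r_bg, c0, sigma_bg, BACKGROUND_WIDTH_SIGMA_MM,
        bg_level * peak, SHAPE_EXPONENT,
    )
    return np.maximum(mound, bg)


def render_pressure_map(
    patch: PatchParams,
    compartment: str,
    grid: GridSpec = GridSpec(),
    margins: CondyleMargins = DEFAULT_MARGINS,
    *,
    threshold: float | None = None,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> PressureMap:
    """Rasterize a contact patch onto a sensel grid.

    The pressure field is the pointwise maximum of two anisotropic
    super-Gaussian components, ``a * exp(-(dr^2/2s_r^2 + dc^2/2s_c^2)^k)``:

    * a narrow *mound* of amplitude ``peak_mpa`` centered at the requested
      fractional craniocaudal peak position (and the mediolateral grid
      center) — the local high-pressure focus whose sensel defines the
      peak-pressure location;
    * a broad *background* at 70% of the peak amplitude centered at
      ``background_fraction`` — the stable load-bearing distribution of the
      compartment.

    The background length scale is solved by bisection so that the contact
    area at the analysis threshold lands within ~5% of the target (up to
    one-sensel quantization); when the target area is smaller than the
    mound's own footprint, the mound length scale is solved instead and no
    background is drawn.  Values are clipped at the saturation pressure;
    ``noise_cv`` adds multiplicative Gaussian sensel noise with that
    coefficient of variation.

    Raises
    ------
    InfeasiblePatchError
        when the target area cannot fit the sensing area.
    """
    thr = grid.sensitivity if threshold is None else float(threshold)
    if patch.area_mm2 > 0.98 * grid.total_area:
        raise InfeasiblePatchError(
            f"target contact area {patch.area_mm2:.1f} mm^2 exceeds the "
            f"{grid.total_area:.1f} mm^2 sensing area"
        )
    if patch.peak_mpa <= thr or patch.area_mm2 < grid.sensel_area:
        pressures = np.zeros((grid.n_rows, grid.n_cols))
    else:
        # the mound is centered on a sensel center so the sensor grid
        # realizes the drawn peak pressure exactly
        r_peak = float(
            np.clip(
                np.round(margins.caudal_row + patch.center_fraction * margins.span),
                0,
                grid.n_rows - 1,
            )
        )
        bg_frac = (
            patch.center_fraction
            if patch.background_fraction is None
            else patch.background_fraction
        )
        r_bg = margins.caudal_row + bg_frac * margins.span
        c0 = float((grid.n_cols - 1) // 2)
        target_n = patch.area_mm2 / grid.sensel_area

        def n_contact(sigma_bg: float) -> int:
            vals = _field(
                grid, sigma_bg, r_peak, r_bg, c0, patch.peak_mpa,
                patch.background_level,
            )
            return int(np.count_nonzero(vals >= thr))

        if n_contact(0.0) >= target_n:
            # target smaller than the default mound footprint: shrink the
            # mound itself (no background)
            def n_mound(sigma: float) -> int:
                vals = _mound(
                    grid, r_peak, c0, sigma, MOUND_ASPECT * sigma,
                    patch.peak_mpa, SHAPE_EXPONENT,
                )
                return int(np.count_nonzero(vals >= thr))

            sigma = _bisect_scale(n_mound, target_n, patch.area_mm2, thr)
            pressures = _mound(
                grid, r_peak, c0, sigma, MOUND_ASPECT * sigma,
                patch.peak_mpa, SHAPE_EXPONENT,
            )
        else:
            sigma_bg = _bisect_scale(n_contact, target_n, patch.area_mm2, thr)
            pressures = _field(
                grid, sigma_bg, r_peak, r_bg, c0, patch.peak_mpa,
                patch.background_level,
            )
        pressures = pressures.copy()
        pressures[pressures < thr] = 0.0

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_cv > 0:
        pressures = pressures * (1.0 + noise_cv * rng.normal(size=pressures.shape))
        pressures = np.clip(pressures, 0.0, None)
    pressures = np.clip(pressures, 0.0, grid.saturation)
    return PressureMap(
        compartment=compartment,
        pressures=pressures,
        row_pitch=grid.row_pitch,
        col_pitch=grid.col_pitch,
        saturation=grid.saturation,
        sensitivity=grid.sensitivity,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatchEffect:
    """Between-specimen distribution of one compartment's patch parameters.

    ``background_level_sd`` controls the contact-field shape heterogeneity
    (background amplitude and centroid jitter); setting it to 0 together
    with the three parameter sds makes every drawn patch identical.
    """

    center_fraction: float
    center_fraction_sd: float
    peak_mpa: float
    peak_mpa_sd: float
    area_mm2: float
    area_mm2_sd: float
    background_level_sd: float = BACKGROUND_LEVEL_SD

    def __post_init__(self):
        for name in ("center_fraction_sd", "peak_mpa_sd", "area_mm2_sd",
                     "background_level_sd"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if not (0.0 <= self.center_fraction <= 1.0):
            raise InputError("center_fraction mean outside [0, 1]")

    def draw(self, rng: np.random.Generator) -> PatchParams:
        frac = rng.normal(self.center_fraction, self.center_fraction_sd)
        peak = rng.normal(self.peak_mpa, self.peak_mpa_sd)
        area = rng.normal(self.area_mm2, self.area_mm2_sd)
        # physical truncation: fractions inside the condyle, positive sizes.
        # The background stays at the condition mean: only the peak focus
        # wanders specimen to specimen.
        level = rng.normal(BACKGROUND_LEVEL, self.background_level_sd)
        jitter = BACKGROUND_CENTER_JITTER_SD if self.background_level_sd > 0 else 0.0
        bg_frac = (
            self.center_fraction
            + BACKGROUND_SKEW
            + rng.normal(0.0, jitter)
        )
        return PatchParams(
            center_fraction=float(np.clip(frac, 0.02, 0.98)),
            peak_mpa=float(max(peak, 0.2)),
            area_mm2=float(max(area, 5.0)),
            background_fraction=float(np.clip(bg_frac, 0.0, 1.0)),
            background_level=float(np.clip(level, *BACKGROUND_LEVEL_BOUNDS)),
        )


@dataclass(frozen=True)
class ConditionEffect:
    """Target distribution of one loading condition: JCS pose mean and
    between-specimen sd (per component) plus per-compartment patch effects."""

    pose_mean: Mapping[str, float]
    pose_sd: Mapping[str, float]
    patches: Mapping[str, PatchEffect]

    def __post_init__(self):
        for m in (self.pose_mean, self.pose_sd):
            missing = [f for f in JcsPose.FIELDS if f not in m]
            if missing:
                raise InputError(f"condition effect missing pose fields {missing}")
        if any(v < 0 for v in self.pose_sd.values()):
            raise InputError("pose sds must be >= 0")
        if set(self.patches) != {"medial", "lateral"}:
            raise InputError("patches must have medial and lateral entries")
        object.__setattr__(self, "pose_mean", dict(self.pose_mean))
        object.__setattr__(self, "pose_sd", dict(self.pose_sd))
        object.__setattr__(self, "patches", dict(self.patches))

    def draw_pose(self, rng: np.random.Generator) -> JcsPose:
        vals = {
            f: rng.normal(self.pose_mean[f], self.pose_sd[f]) for f in JcsPose.FIELDS
        }
        vals["flexion_extension"] = float(np.clip(vals["flexion_extension"], 1.0, 180.0))
        return JcsPose(**vals)


def _pose(fe, vv, ie, cacr, ml, dp):
    return dict(zip(JcsPose.FIELDS, (fe, vv, ie, cacr, ml, dp)))


def default_condition_effects() -> dict[tuple[str, str], ConditionEffect]:
    """Default cohort configuration: the four study conditions.

    Pose means/sds and per-compartment contact-patch targets (craniocaudal
    peak location as a fraction, peak pressure MPa, contact area mm^2)
    encode the measured condition summaries of the modelled experiment:
    intact and CCL-transected stifles at the stance-phase (~135 deg) and
    high-flexion (~90 deg) angles.
    """
    return {
        ("135", "intact"): ConditionEffect(
            pose_mean=_pose(138.5, 10.4, 13.8, 10.2, 9.1, 4.6),
            pose_sd=_pose(3.5, 2.8, 3.6, 3.9, 5.2, 2.2),
            patches={
                "medial": PatchEffect(0.50, 0.15, 3.1, 0.6, 177.0, 19.0),
                "lateral": PatchEffect(0.61, 0.09, 3.0, 0.5, 138.0, 26.0),
            },
        ),
        ("135", "transected"): ConditionEffect(
            pose_mean=_pose(142.7, 5.3, -4.6, 25.1, 10.6, -2.5),
            pose_sd=_pose(2.8, 2.3, 5.7, 4.9, 4.7, 2.5),
            patches={
                "medial": PatchEffect(0.16, 0.03, 5.6, 1.2, 73.0, 13.0),
                "lateral": PatchEffect(0.23, 0.09, 4.1, 1.4, 104.0, 24.0),
            },
        ),
        ("90", "intact"): ConditionEffect(
            pose_mean=_pose(101.5, 2.8, 10.7, 10.4, -0.7, 3.8),
            pose_sd=_pose(5.5, 7.4, 3.6, 3.6, 10.8, 3.6),
            patches={
                "medial": PatchEffect(0.39, 0.07, 4.0, 0.8, 174.0, 22.0),
                "lateral": PatchEffect(0.49, 0.05, 4.0, 0.4, 142.0, 20.0),
            },
        ),
        ("90", "transected"): ConditionEffect(
            pose_mean=_pose(102.7, 2.4, -8.3, 11.0, -1.1, 3.6),
            pose_sd=_pose(7.6, 7.3, 4.2, 4.0, 10.8, 3.1),
            patches={
                "medial": PatchEffect(0.40, 0.08, 4.1, 0.9, 155.0, 16.0),
                "lateral": PatchEffect(0.52, 0.10, 3.5, 0.8, 135.0, 30.0),
            },
        ),
    }


@dataclass(frozen=True)
class ConditionData:
    """Rendered inputs plus ground truth for one specimen x condition."""

    label: str
    flexion_label: str
    ccl_status: str
    true_pose: JcsPose
    true_patches: Mapping[str, PatchParams]
    femur_markers_lab: MarkerTriad
    tibia_markers_lab: MarkerTriad
    maps: Mapping[str, PressureMap]
    margins: Mapping[str, CondyleMargins]

    def __post_init__(self):
        object.__setattr__(self, "true_patches", dict(self.true_patches))
        object.__setattr__(self, "maps", dict(self.maps))
        object.__setattr__(self, "margins", dict(self.margins))

    @property
    def flexion_nominal_deg(self) -> float:
        return float(self.flexion_label)


@dataclass(frozen=True)
class SyntheticCohort:
    """A complete synthetic study: specimens, rendered condition inputs and
    the ground-truth sidecar.  Regeneration with the same seed is
    byte-identical."""

    specimens: tuple
    conditions: Mapping[str, tuple]  # specimen_id -> tuple[ConditionData]
    seed: int
    grid: GridSpec

    def __post_init__(self):
        object.__setattr__(self, "specimens", tuple(self.specimens))
        object.__setattr__(
            self, "conditions", {k: tuple(v) for k, v in self.conditions.items()}
        )

    @property
    def n(self) -> int:
        return len(self.specimens)


def make_cohort(
    n: int = 8,
    effects: Mapping[tuple[str, str], ConditionEffect] | None = None,
    seed: int = 0,
    template: SpecimenTemplate = SpecimenTemplate(),
    grid: GridSpec = GridSpec(),
    margins: CondyleMargins = DEFAULT_MARGINS,
    noise_sd: float = DIGITIZER_NOISE_SD_MM,
    map_noise_cv: float = 0.0,
) -> SyntheticCohort:
    """Generate a full synthetic cohort of ``n`` specimens x 4 conditions.

    Per-specimen condition effects are drawn independently from the
    :class:`ConditionEffect` distributions (between-specimen variation is
    Gaussian, truncated at physical bounds).  Defaults follow the modelled
    study: n = 8 limbs, digitizer noise sd 0.23 mm.  Deterministic given
    ``seed``.
    """
    if n < 1:
        raise InputError("cohort needs at least one specimen")
    effects = default_condition_effects() if effects is None else dict(effects)
    rng = np.random.default_rng(seed)
    specimens = []
    conditions: dict[str, list] = {}
    for i in range(n):
        sid = f"S{i + 1:02d}"
        side = "right" if i % 2 == 0 else "left"
        spec = make_specimen(template, rng, specimen_id=sid, side=side)
        specimens.append(spec)
        cond_list = []
        for flexion_label, status in CONDITIONS:
            eff = effects[(flexion_label, status)]
            pose = eff.draw_pose(rng)
            fm, tm = render_condition(spec, pose, noise_sd=noise_sd, seed=rng)
            patches = {}
            maps = {}
            for compartment in ("medial", "lateral"):
                p = eff.patches[compartment].draw(rng)
                patches[compartment] = p
                maps[compartment] = render_pressure_map(
                    p,
                    compartment,
                    grid=grid,
                    margins=margins,
                    noise_cv=map_noise_cv,
                    seed=rng,
                )
            cond_list.append(
                ConditionData(
                    label=f"{flexion_label}_{status}",
                    flexion_label=flexion_label,
                    ccl_status=status,
                    true_pose=pose,
                    true_patches=patches,
                    femur_markers_lab=fm,
                    tibia_markers_lab=tm,
                    maps=maps,
                    margins={"medial": margins, "lateral": margins},
                )
            )
        conditions[sid] = cond_list
    return SyntheticCohort(
        specimens=tuple(specimens), conditions=conditions, seed=seed, grid=grid
    )
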