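# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package. Units are millimetres, degrees, MPa and N
throughout; angles are degrees at every public interface (radians only
internally).

## Rigid registration

Marker triads (three nylon screws per bone) are digitized once in the
CT/bone frame and once per loading condition in the lab. `fit_rigid` solves
the least-squares rigid transform (Kabsch/SVD with a reflection guard: the
singular vector of the smallest singular value is flipped when the optimal
orthogonal map would be a reflection) for any n ≥ 3 matched points, and
reports the RMS point residual. Sources whose second principal extent is
below 1e-6 mm are rejected as collinear — the rotation about the point line
would be unidentifiable. `transfer_landmarks` chains this fit to carry all
anatomical landmarks into the lab frame.

With exact inputs the residual is numerically zero (≤ 1e-10 mm is asserted
over 1,000 random rigid motions). With the digitizer's 0.23 mm accuracy —
read as a 1-sd isotropic Gaussian per coordinate, a stated assumption —
the median translation error of a registered marker triad is ≈ 0.29 mm for
the marker geometries used here (frozen from a pre-build Monte-Carlo run of
an independently coded oracle, scipy's `align_vectors`).

## Anatomic frames and the joint coordinate system

All frames use the right-handed axis triple (ML, AP, PD) = (medial,
cranial, proximal). Left limbs are mirrored (x ↦ −x) at file ingest so a
single sign convention holds internally; the writer mirrors back.

* **Femur** — origin at the midpoint of the medial/lateral condyle centers;
  ML along the transcondylar line toward medial; PD the component of
  origin→femoral-head-center orthogonal to ML (Gram–Schmidt); AP = PD × ML.
* **Tibia** — origin at the midpoint of the condyle outer edges; PD from
  the distal tibia center toward that midpoint (primary axis, because it is
  the body-fixed tibial axis of the joint coordinate system); ML the
  component of the lateral→medial edge direction orthogonal to PD;
  AP = PD × ML.

The published experiment names these landmarks but not an axis recipe;
the recipes above are the simplest construction consistent with
Grood–Suntay usage, and all frame constructions are equivariant under rigid
motion of their input landmarks (property-tested).

Rotations use body-fixed axes in the order flexion/extension (femoral ML),
adduction/abduction (floating axis), internal/external rotation (tibial
PD) — an intrinsic X-Y-Z Euler decomposition of the relative rotation in
(ML, AP, PD) coordinates. Flexion/extension is reported as the *included
joint angle*: collinear long axes give 180°, physiologic flexion tilts the
tibial long axis cranially (a negative rotation about the medial axis), so
the reported angle is 180° + α. This matches goniometric practice and makes
stance-phase values (~138°) directly comparable to protocol targets.
Positive varus/valgus is varus; positive internal/external is external
tibial rotation. Near gimbal lock (|femoral ML · tibial PD| > 0.99, i.e.
the floating axis ill-defined) the decomposition raises a
singular-configuration error reporting the alignment rather than returning
unstable angles. `jcs_compose` is the exact inverse; round trips are
asserted to 1e-8° over a 1,000-pose grid.

Translations are measured from the CCL origin (femur) to its insertion
(tibia) and resolved in the tibial anatomic frame; positive components are
cranial, medial and distracted (the distraction direction is −PD). The
metric is invariant under any rigid motion applied jointly to the points
and the frame.

## Contact metrics

A pressure map is a per-compartment sensel grid, row 0 = caudal-most row.
A sensel is in contact iff its pressure ≥ threshold; the default threshold
is the sensor sensitivity (0.01 MPa) on the reading that contact area is
the *area of contact*, not the calibrated-range floor (0.5 MPa) — the
threshold is one CLI flag away for the alternative reading. Contact area is
the in-contact count × sensel area; mean pressure averages over in-contact
sensels only; the peak is the in-contact maximum with ties broken
deterministically toward the most caudal row, then the lowest column.

Peak-pressure location is (peak row − caudal margin)/(cranial margin −
caudal margin), clamped to [0, 1] with a logged warning when the peak falls
outside the digitized margins. Regional forces split the margin-to-margin
span into three equal bands; each in-contact sensel is assigned by its
row-center coordinate, and sensels outside the span are clamped to the
nearest terminal band with a warning — discarding them would silently lose
force and break the conservation identity (cranial + central + caudal =
total, exact by construction since the total is the same summand set).
Saturated sensels (= 30 MPa) are included in every metric and surfaced
through a QC counter. Joint (medial + lateral) totals add areas and forces;
the joint peak is the larger compartment peak and the joint mean is total
force / total area.

The default fixture grid is 26 × 10 sensels (row pitch 30.9/26 mm, column
pitch 1.2 mm) tiling the 30.9 × 12.0 mm sensing area; the true sensel count
of the instrument is not public, and both dimensions are configurable.

## Statistics

The design is fully paired (every limb serves as its own control). Scalar
metrics use the paired Student t (t = mean(d)/(sd(d)/√n), df = n − 1,
two-sided); zero-variance non-zero differences raise a degenerate-sample
error, while an exactly null sample returns (t, p) = (0, 1). Regional
forces are fitted per compartment with the blocked linear model
`force ~ status × region + specimen` (OLS, specimen as a fixed block),
whose status × region interaction F-test is reported; the per-region status
contrasts, however, use the *region-specific* error stratum (the paired
differences of that region, df = n − 1) rather than the pooled residual.
Regional forces are heteroscedastic by orders of magnitude — an unloaded
region carries ~0 ± 1 N next to a loaded one at ~140 ± 50 N — and pooled
contrasts measured 4–8% type-I error at α = 0.01 in null simulations, while
the stratified contrasts are calibrated (≤ 2.3% over 1,000 null cohorts)
and reduce exactly to the paired t when a region is analyzed alone.
α = 0.01 throughout; no multiple-testing correction beyond that strict
threshold. Specimens are analyzed at the limb level; the generator carries
no dog-level pairing structure, so no dog-averaged analysis is offered.

## Synthetic-specimen generator

The generator is the inverse of the pipeline, so that every stage is
testable without cadaver data.

**Geometry.** An idealized stifle template (condyle spacing 25 mm, femur
200 mm, tibia 210 mm, condyle span 30 mm, tibial plateau angle 23° — sized
for a ~30 kg dog) is laid out in canonical anatomic coordinates, then each
bone is scrambled by an arbitrary rigid motion to form its CT frame, as for
a real scan. `render_condition` places the femur at an arbitrary lab pose,
composes the requested joint rotation, and positions the tibia so the CCL
origin→insertion vector carries the requested translations; markers are
then perturbed with 0.23 mm Gaussian noise. At zero noise the pipeline
recovers the pose to ≤ 1e-9 (asserted); noisy recovery is unbiased with
spread matching the registration oracle.

**Pressure fields.** Each compartment's field is the pointwise maximum of
two anisotropic super-Gaussians `a·exp(−(Δr²/2s_r² + Δc²/2s_c²)^k)` with
shape exponent k = 2.5 (a plain Gaussian gives an unrealistic mean/peak
pressure ratio of ~0.17; k = 2.5 flattens the mound toward the measured
~0.4):

* a narrow **mound** (s_r = 2.2 mm, aspect 0.8) at the drawn peak position,
  snapped to the nearest sensel center so the grid realizes the drawn peak
  pressure exactly;
* a broad **background** (ML scale 2.6 mm, amplitude 0.80 ± 0.12 of the
  peak, truncated to [0.5, 0.95]) centered at the *condition mean* location
  plus a small cranial offset (+0.04 of condyle length) and a per-specimen
  centroid jitter (sd 0.04).

The separation is the model's central structural assumption: between
specimens the *peak* wanders (local cartilage/meniscus topography; its sd
is the published peak-location scatter) over a *stable* load-bearing
distribution (whole-joint alignment). A single mound carrying the full
peak-location scatter makes the regional forces knife-edge functions of the
drawn center and their induced sds ~2–3× too large. The background length
scale is solved by bisection (a monotone step function of scale) so the
contact area lands within ~5% of the target, up to one-sensel quantization;
targets smaller than the mound footprint shrink the mound instead.
Background shape constants were calibrated once against the published
regional-force and mean-pressure summaries and then frozen.

**Cohorts.** `make_cohort` draws per-specimen, per-condition poses and
patch parameters independently from Gaussians truncated at physical bounds
(areas > 0, fractions in [0, 1], flexion in (0°, 180°]), with defaults
encoding the four study conditions verbatim (n = 8 limbs). A fixed
PCG64 stream seeded by the caller makes regeneration byte-identical.

**What passing tests do and do not show.** The generator emulates the
*statistical* structure of the study — marginal means/sds per condition,
digitizer noise, grid quantization — not real contact physics: fields are
smooth two-component mounds without meniscal geometry or sensor
crosstalk/drift, sensel noise is off by default (multiplicative noise is
available but biases extreme-value statistics like the peak), and
kinematic and contact effects are drawn independently, as are the four
conditions within a specimen (the real within-specimen correlation
structure is unknowable from published summaries). Tests passing on
synthetic cohorts therefore validate the *pipeline's* correctness and
calibration, not the biological effect sizes. One known consequence: the
published 90° condition summaries differ slightly between intact and
transected limbs, so a generator that encodes them verbatim contains real
(if small) 90° effects, and a calibrated test flags them in a nontrivial
fraction of cohorts even though the original study reported no significant
90° changes.

## Pipeline and QC

`run_study` requires ≥ 2 specimens with all four conditions and both
compartment maps each, and fails with an explicit list of missing
specimen/condition inputs otherwise. Per specimen × condition it persists
the full pose and metric row; every summary-table cell is recomputable from
those intermediates (asserted), and re-running on the same inputs is
deterministic. QC covers the 50:50 ± 10% medial:lateral seating criterion
for intact stance conditions, saturated-sensel counts, and
outside-margin sensel counts; warnings are logged and tabulated, never
dropped. Interchange formats are landmark JSON, header-annotated map CSV
(bit-faithful round trip via `repr` floats), tidy CSV for results and JSON
for the report; heat-map PNG export is a convenience only.
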