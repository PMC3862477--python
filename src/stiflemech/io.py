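"""File formats and schema validation.

Interchange formats are plain text:

* **Landmark/marker JSON** — one document per specimen::

      {"specimen_id": ..., "side": "left"|"right",
       "bones": {"femur": {"landmarks_ct": {name: [x, y, z], ...},
                           "markers_ct": [[x, y, z] x 3]},
                 "tibia": {...}},
       "conditions": [{"label": ..., "flexion_nominal_deg": ...,
                       "ccl_status": "intact"|"transected",
                       "markers_lab": {"femur": [[x, y, z] x 3],
                                       "tibia": [[x, y, z] x 3]}}, ...]}

  Coordinates are mm.  Left limbs are stored in their native (mirrored)
  handedness; the reader negates the x (mediolateral) coordinate for
  ``side == "left"`` so that the in-memory representation always uses one
  canonical handedness, and the writer mirrors back symmetrically.

* **Pressure-map CSV** — ``# key=value`` header lines (compartment,
  row_pitch_mm, col_pitch_mm, caudal_row, cranial_row, optionally
  saturation_mpa / sensitivity_mpa) followed by the pressure grid, one row
  per line, row 0 = caudal-most.  Floats are written with ``repr`` so the
  write -> read round trip is bit-faithful.

* Long-format results CSV (pandas) and a nested report JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .contact import CondyleMargins, PressureMap
from .errors import ValidationError
from .kinematics import (
    FEMUR_LANDMARK_NAMES,
    TIBIA_LANDMARK_NAMES,
    BoneLandmarks,
    MarkerTriad,
    Point3,
)

__all__ = [
    "SpecimenRecord",
    "ConditionRecord",
    "write_specimen_json",
    "read_specimen_json",
    "write_pressure_map_csv",
    "read_pressure_map_csv",
    "cohort_to_records",
    "write_cohort",
]


class ConditionRecord:
    """One loading condition of a specimen: lab marker triads and, when
    present, the per-compartment pressure maps."""

    def __init__(
        self,
        label: str,
        flexion_nominal_deg: float,
        ccl_status: str,
        femur_markers_lab: MarkerTriad,
        tibia_markers_lab: MarkerTriad,
        maps: dict[str, PressureMap] | None = None,
        margins: dict[str, CondyleMargins] | None = None,
    ):
        if ccl_status not in ("intact", "transected"):
            raise ValidationError(f"ccl_status must be intact|transected, got {ccl_status!r}")
        self.label = label
        self.flexion_nominal_deg = float(flexion_nominal_deg)
        self.ccl_status = ccl_status
        self.femur_markers_lab = femur_markers_lab
        self.tibia_markers_lab = tibia_markers_lab
        self.maps = maps or {}
        self.margins = margins or {}


class SpecimenRecord:
    """In-memory, canonical-handedness view of one specimen's inputs."""

    def __init__(
        self,
        specimen_id: str,
        side: str,
        femur_landmarks: BoneLandmarks,
        tibia_landmarks: BoneLandmarks,
        femur_markers: MarkerTriad,
        tibia_markers: MarkerTriad,
        conditions: list[ConditionRecord],
    ):
        self.specimen_id = specimen_id
        self.side = side
        self.femur_landmarks = femur_landmarks
        self.tibia_landmarks = tibia_landmarks
        self.femur_markers = femur_markers
        self.tibia_markers = tibia_markers
        self.conditions = list(conditions)


def _mirror(coords: np.ndarray) -> np.ndarray:
    out = np.array(coords, dtype=float)
    out[..., 0] = -out[..., 0]
    return out


def _coords_out(a: np.ndarray, mirror: bool) -> list:
    a = _mirror(a) if mirror else np.asarray(a, dtype=float)
    return [[float(v) for v in row] for row in np.atleast_2d(a)]


def _point_list(obj: Any, where: str, n_expected: int | None = None) -> np.ndarray:
    try:
        a = np.asarray(obj, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{where}: not a numeric coordinate list ({exc})")
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValidationError(f"{where}: expected a list of [x, y, z] triples")
    if n_expected is not None and a.shape[0] != n_expected:
        raise ValidationError(f"{where}: expected {n_expected} points, got {a.shape[0]}")
    if not np.all(np.isfinite(a)):
        raise ValidationError(f"{where}: non-finite coordinate")
    return a


def _require(d: dict, key: str, where: str) -> Any:
    if not isinstance(d, dict) or key not in d:
        raise ValidationError(f"{where}: missing required key {key!r}")
    return d[key]


# ---------------------------------------------------------------------------
# landmark JSON
# ---------------------------------------------------------------------------


def write_specimen_json(record: SpecimenRecord, path: str | Path) -> None:
    """Serialize a specimen (mirroring left limbs back to native handedness)."""
    mirror = record.side == "left"

    def bone(landmarks: BoneLandmarks, markers: MarkerTriad) -> dict:
        return {
            "landmarks_ct": {
                name: _coords_out(p.as_array(), mirror)[0]
                for name, p in landmarks.points.items()
            },
            "markers_ct": _coords_out(markers.as_array(), mirror),
        }

    doc = {
        "specimen_id": record.specimen_id,
        "side": record.side,
        "bones": {
            "femur": bone(record.femur_landmarks, record.femur_markers),
            "tibia": bone(record.tibia_landmarks, record.tibia_markers),
        },
        "conditions": [
            {
                "label": c.label,
                "flexion_nominal_deg": c.flexion_nominal_deg,
                "ccl_status": c.ccl_status,
                "markers_lab": {
                    "femur": _coords_out(c.femur_markers_lab.as_array(), mirror),
                    "tibia": _coords_out(c.tibia_markers_lab.as_array(), mirror),
                },
            }
            for c in record.conditions
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def read_specimen_json(path: str | Path) -> SpecimenRecord:
    """Parse and validate a specimen document, normalizing left limbs to the
    canonical handedness (mediolateral coordinate mirrored)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path.name}: invalid JSON at line {exc.lineno}: {exc.msg}")
    where = path.name
    sid = _require(doc, "specimen_id", where)
    side = _require(doc, "side", where)
    if side not in ("left", "right"):
        raise ValidationError(f"{where}: side must be left|right, got {side!r}")
    mirror = side == "left"

    def coords_in(obj, ctx, n=None) -> np.ndarray:
        a = _point_list(obj, ctx, n)
        return _mirror(a) if mirror else a

    bones = _require(doc, "bones", where)
    required_names = {"femur": FEMUR_LANDMARK_NAMES, "tibia": TIBIA_LANDMARK_NAMES}
    parsed: dict[str, tuple[BoneLandmarks, MarkerTriad]] = {}
    for role in ("femur", "tibia"):
        b = _require(bones, role, f"{where}: bones")
        lm = _require(b, "landmarks_ct", f"{where}: bones.{role}")
        missing = [n for n in required_names[role] if n not in lm]
        if missing:
            raise ValidationError(f"{where}: bones.{role}.landmarks_ct missing {missing}")
        pts = {}
        for name in required_names[role]:
            a = coords_in([lm[name]], f"{where}: {role}.{name}", 1)[0]
            pts[name] = Point3.from_array(a, f"ct_{role}")
        landmarks = BoneLandmarks(role=role, points=pts)
        mk = coords_in(
            _require(b, "markers_ct", f"{where}: bones.{role}"),
            f"{where}: {role}.markers_ct",
            3,
        )
        parsed[role] = (landmarks, MarkerTriad.from_array(mk, f"ct_{role}"))

    conditions = []
    for i, c in enumerate(_require(doc, "conditions", where)):
        ctx = f"{where}: conditions[{i}]"
        ml = _require(c, "markers_lab", ctx)
        conditions.append(
            ConditionRecord(
                label=str(_require(c, "label", ctx)),
                flexion_nominal_deg=float(_require(c, "flexion_nominal_deg", ctx)),
                ccl_status=str(_require(c, "ccl_status", ctx)),
                femur_markers_lab=MarkerTriad.from_array(
                    coords_in(_require(ml, "femur", ctx), f"{ctx}.femur", 3), "lab"
                ),
                tibia_markers_lab=MarkerTriad.from_array(
                    coords_in(_require(ml, "tibia", ctx), f"{ctx}.tibia", 3), "lab"
                ),
            )
        )
    fl, fm = parsed["femur"]
    tl, tm = parsed["tibia"]
    return SpecimenRecord(str(sid), side, fl, tl, fm, tm, conditions)


# ---------------------------------------------------------------------------
# pressure-map CSV
# ---------------------------------------------------------------------------

_MAP_HEADER_KEYS = {
    "compartment",
    "row_pitch_mm",
    "col_pitch_mm",
    "caudal_row",
    "cranial_row",
    "saturation_mpa",
    "sensitivity_mpa",
}


def write_pressure_map_csv(
    pmap: PressureMap, margins: CondyleMargins, path: str | Path
) -> None:
    lines = [
        f"# compartment={pmap.compartment}",
        f"# row_pitch_mm={pmap.row_pitch!r}",
        f"# col_pitch_mm={pmap.col_pitch!r}",
        f"# caudal_row={margins.caudal_row!r}",
        f"# cranial_row={margins.cranial_row!r}",
        f"# saturation_mpa={pmap.saturation!r}",
        f"# sensitivity_mpa={pmap.sensitivity!r}",
    ]
    lines += [",".join(repr(float(v)) for v in row) for row in pmap.pressures]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pressure_map_csv(path: str | Path) -> tuple[PressureMap, CondyleMargins]:
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if rows:
                raise ValidationError(
                    f"{path.name}:{lineno}: header line after grid data"
                )
            body = line.lstrip("#").strip()
            if "=" not in body:
                raise ValidationError(
                    f"{path.name}:{lineno}: malformed header {line!r} (need key=value)"
                )
            key, _, value = body.partition("=")
            key = key.strip()
            if key not in _MAP_HEADER_KEYS:
                raise ValidationError(f"{path.name}:{lineno}: unknown header key {key!r}")
            header[key] = value.strip()
        else:
            try:
                rows.append([float(v) for v in line.split(",")])
            except ValueError as exc:
                raise ValidationError(f"{path.name}:{lineno}: bad grid value ({exc})")
    for key in ("compartment", "row_pitch_mm", "col_pitch_mm", "caudal_row", "cranial_row"):
        if key not in header:
            raise ValidationError(f"{path.name}: missing required header {key!r}")
    if not rows:
        raise ValidationError(f"{path.name}: no pressure grid rows")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValidationError(f"{path.name}: ragged grid rows (widths {sorted(widths)})")
    try:
        pmap = PressureMap(
            compartment=header["compartment"],
            pressures=np.array(rows, dtype=float),
            row_pitch=float(header["row_pitch_mm"]),
            col_pitch=float(header["col_pitch_mm"]),
            saturation=float(header.get("saturation_mpa", 30.0)),
            sensitivity=float(header.get("sensitivity_mpa", 0.01)),
        )
        margins = CondyleMargins(
            caudal_row=float(header["caudal_row"]),
            cranial_row=float(header["cranial_row"]),
        )
        margins.check_within(pmap)
    except Exception as exc:
        raise ValidationError(f"{path.name}: {exc}") from exc
    return pmap, margins


# ---------------------------------------------------------------------------
# cohort export
# ---------------------------------------------------------------------------


def cohort_to_records(cohort) -> list[SpecimenRecord]:
    """View a :class:`~stiflemech.synthetic.SyntheticCohort` as the specimen
    records the pipeline consumes (no files involved)."""
    records = []
    for spec in cohort.specimens:
        conds = [
            ConditionRecord(
                label=c.label,
                flexion_nominal_deg=c.flexion_nominal_deg,
                ccl_status=c.ccl_status,
                femur_markers_lab=c.femur_markers_lab,
                tibia_markers_lab=c.tibia_markers_lab,
                maps=dict(c.maps),
                margins=dict(c.margins),
            )
            for c in cohort.conditions[spec.specimen_id]
        ]
        records.append(
            SpecimenRecord(
                specimen_id=spec.specimen_id,
                side=spec.side,
                femur_landmarks=spec.femur_landmarks,
                tibia_landmarks=spec.tibia_landmarks,
                femur_markers=spec.femur_markers,
                tibia_markers=spec.tibia_markers,
                conditions=conds,
            )
        )
    return records


def write_cohort(cohort, outdir: str | Path) -> None:
    """Write a synthetic cohort to disk: one landmark JSON per specimen under
    ``specimens/``, map CSVs under ``maps/`` and a ``ground_truth.csv``."""
    outdir = Path(outdir)
    (outdir / "specimens").mkdir(parents=True, exist_ok=True)
    (outdir / "maps").mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for record, spec in zip(cohort_to_records(cohort), cohort.specimens):
        write_specimen_json(record, outdir / "specimens" / f"{record.specimen_id}.json")
        for c in cohort.conditions[spec.specimen_id]:
            for compartment, pmap in c.maps.items():
                write_pressure_map_csv(
                    pmap,
                    c.margins[compartment],
                    outdir / "maps" / f"{spec.specimen_id}_{c.label}_{compartment}.csv",
                )
            row = {
                "specimen": spec.specimen_id,
                "condition": c.label,
                "flexion": c.flexion_label,
                "ccl_status": c.ccl_status,
            }
            for f in type(c.true_pose).FIELDS:
                row[f"true_{f}"] = getattr(c.true_pose, f)
            for compartment, p in c.true_patches.items():
                row[f"true_{compartment}_center_fraction"] = p.center_fraction
                row[f"true_{compartment}_peak_mpa"] = p.peak_mpa
                row[f"true_{compartment}_area_mm2"] = p.area_mm2
            truth_rows.append(row)
    pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.csv", index=False)
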