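"""Study orchestration: kinematics + contact + stats end to end.

:func:`run_study` reads per-specimen landmark JSON and per-compartment
pressure-map CSVs, reconstructs the six-component femorotibial pose and the
contact metrics of every specimen x condition, runs the paired intact vs.
CCL-transected comparisons at each flexion angle, and emits analogs of the
study's three summary tables plus per-specimen intermediates and QC:

* table 1 — contact area, peak/mean pressure and peak-pressure location per
  compartment and condition (mean +/- sd, significance flags at p < alpha);
* table 2 — regional (cranial/central/caudal) contact forces with the
  per-region GLM status contrasts;
* table 3 — the six pose components per condition;
* QC — medial:lateral force balance of every intact stance-phase specimen
  (the 50:50 +/- 10% seating criterion), saturated-sensel counts, and
  counts of in-contact sensels outside the digitized condyle margins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contact as ct
from . import stats as st
from .errors import InputError, MissingDataError, ValidationError
from .io import SpecimenRecord, read_pressure_map_csv, read_specimen_json
from .kinematics import JcsPose, compute_pose

__all__ = [
    "StudyConfig",
    "StudyReport",
    "FLEXION_LABELS",
    "load_study_inputs",
    "analyze_records",
    "run_study",
    "significance_flags",
    "matches_caudal_shift_pattern",
    "export_heatmap",
]

logger = logging.getLogger(__name__)

FLEXION_LABELS = ("135", "90")
STATUS_LEVELS = ("intact", "transected")

#: scalar metric columns compared with paired t-tests
SCALAR_METRICS = (
    ["area_total", "area_medial", "area_lateral"]
    + ["peak_total", "peak_medial", "peak_lateral"]
    + ["mean_total", "mean_medial", "mean_lateral"]
    + ["loc_medial", "loc_lateral"]
    + list(JcsPose.FIELDS)
)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run."""

    input_dir: str
    output_dir: str | None = None
    threshold: float | None = None  # contact threshold, MPa; None = sensitivity
    alpha: float = st.ALPHA
    seed: int = 0  # reserved for resampling extensions; the analysis itself
    # is deterministic

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise InputError(f"alpha must lie in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "input_dir" not in doc:
            raise ValidationError(f"{path}: config requires input_dir")
        return cls(**doc)


@dataclass
class StudyReport:
    """All study outputs; every summary cell is recomputable from the
    per-condition and regional-force intermediates it carries."""

    per_condition: pd.DataFrame  # one row per specimen x condition (wide)
    regional: pd.DataFrame  # long regional force rows
    scalar_tests: pd.DataFrame  # paired t per metric x flexion
    regional_tests: pd.DataFrame  # GLM contrasts per compartment x region x flexion
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    qc: pd.DataFrame
    alpha: float

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "per_condition",
            "regional",
            "scalar_tests",
            "regional_tests",
            "table1",
            "table2",
            "table3",
            "qc",
        ):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        summary = {
            "alpha": self.alpha,
            "n_specimens": int(self.per_condition["specimen"].nunique()),
            "significant": {
                f"{r.metric}@{r.flexion}": bool(r.significant)
                for r in self.scalar_tests.itertuples()
            },
            "qc_balance_failures": int((~self.qc["balanced"]).sum()),
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")


def _flexion_label(nominal_deg: float) -> str:
    label = str(int(round(nominal_deg)))
    if label not in FLEXION_LABELS:
        raise ValidationError(
            f"flexion_nominal_deg {nominal_deg} does not match a study flexion "
            f"label {FLEXION_LABELS}"
        )
    return label


def load_study_inputs(input_dir: str | Path) -> list[SpecimenRecord]:
    """Read every ``specimens/*.json`` and attach the matching
    ``maps/{specimen}_{condition}_{compartment}.csv`` grids."""
    input_dir = Path(input_dir)
    spec_dir = input_dir / "specimens"
    if not spec_dir.is_dir():
        raise MissingDataError(f"no specimens/ directory under {input_dir}")
    records = []
    for path in sorted(spec_dir.glob("*.json")):
        record = read_specimen_json(path)
        for cond in record.conditions:
            for compartment in ("medial", "lateral"):
                map_path = (
                    input_dir
                    / "maps"
                    / f"{record.specimen_id}_{cond.label}_{compartment}.csv"
                )
                if map_path.exists():
                    pmap, margins = read_pressure_map_csv(map_path)
                    if pmap.compartment != compartment:
                        raise ValidationError(
                            f"{map_path.name}: header compartment "
                            f"{pmap.compartment!r} contradicts the file name"
                        )
                    cond.maps[compartment] = pmap
                    cond.margins[compartment] = margins
        records.append(record)
    if not records:
        raise MissingDataError(f"no specimen JSON files under {spec_dir}")
    return records


def _check_complete(records: list[SpecimenRecord]) -> None:
    if len(records) < 2:
        raise MissingDataError(
            f"paired analysis needs >= 2 specimens, got {len(records)}"
        )
    expected = {(f, s) for f in FLEXION_LABELS for s in STATUS_LEVELS}
    missing = []
    for rec in records:
        seen = set()
        for cond in rec.conditions:
            key = (_flexion_label(cond.flexion_nominal_deg), cond.ccl_status)
            seen.add(key)
            if not {"medial", "lateral"} <= set(cond.maps):
                missing.append(f"{rec.specimen_id}/{cond.label}: pressure map(s)")
        for f, s in sorted(expected - seen):
            missing.append(f"{rec.specimen_id}: condition {f}/{s}")
    if missing:
        raise MissingDataError("incomplete study inputs: " + "; ".join(missing))


def _outside_margin_count(pmap, margins, threshold) -> int:
    mask = ct.contact_mask(pmap, threshold)
    rows = np.nonzero(mask)[0].astype(float)
    u = (rows - margins.caudal_row) / margins.span
    return int(np.sum((u < 0.0) | (u > 1.0)))


def analyze_records(
    records: list[SpecimenRecord],
    alpha: float = st.ALPHA,
    threshold: float | None = None,
) -> StudyReport:
    """Run the full analysis on in-memory specimen records."""
    _check_complete(records)
    rows, force_rows, qc_rows = [], [], []
    for rec in records:
        for cond in rec.conditions:
            flexion = _flexion_label(cond.flexion_nominal_deg)
            pose = compute_pose(
                rec.femur_landmarks,
                rec.tibia_landmarks,
                rec.femur_markers,
                cond.femur_markers_lab,
                rec.tibia_markers,
                cond.tibia_markers_lab,
            )
            row = {
                "specimen": rec.specimen_id,
                "side": rec.side,
                "condition": cond.label,
                "flexion": flexion,
                "ccl_status": cond.ccl_status,
            }
            row.update({f: getattr(pose, f) for f in JcsPose.FIELDS})

            metrics = {}
            n_outside = 0
            for compartment in ("medial", "lateral"):
                pmap = cond.maps[compartment]
                margins = cond.margins[compartment]
                m = ct.compartment_metrics(pmap, margins, threshold)
                metrics[compartment] = m
                row[f"area_{compartment}"] = m.area
                row[f"peak_{compartment}"] = m.peak_pressure
                row[f"mean_{compartment}"] = m.mean_pressure
                row[f"loc_{compartment}"] = m.peak_location
                row[f"force_{compartment}"] = m.total_force
                n_outside += _outside_margin_count(pmap, margins, threshold)
                for region, force in m.forces.items():
                    force_rows.append(
                        {
                            "specimen": rec.specimen_id,
                            "flexion": flexion,
                            "ccl_status": cond.ccl_status,
                            "compartment": compartment,
                            "region": region,
                            "force": force,
                        }
                    )
            totals = ct.joint_totals(metrics["medial"], metrics["lateral"])
            row["area_total"] = totals["area"]
            row["peak_total"] = totals["peak_pressure"]
            row["mean_total"] = totals["mean_pressure"]
            row["force_total"] = totals["total_force"]
            rows.append(row)

            ratio = row["force_medial"] / row["force_total"] if row["force_total"] else np.nan
            balance_applies = flexion == "135" and cond.ccl_status == "intact"
            balanced = bool(ct.is_balanced(ratio)) if np.isfinite(ratio) else False
            if balance_applies and not balanced:
                logger.warning(
                    "QC: specimen %s intact stance medial:lateral ratio %.2f "
                    "outside 0.5 +/- 0.1", rec.specimen_id, ratio,
                )
            qc_rows.append(
                {
                    "specimen": rec.specimen_id,
                    "condition": cond.label,
                    "ml_ratio": ratio,
                    "balance_check_applies": balance_applies,
                    "balanced": balanced,
                    "n_saturated": metrics["medial"].n_saturated
                    + metrics["lateral"].n_saturated,
                    "n_outside_margins": n_outside,
                }
            )

    per_condition = pd.DataFrame(rows).sort_values(["specimen", "condition"]).reset_index(drop=True)
    regional = pd.DataFrame(force_rows)
    qc = pd.DataFrame(qc_rows).sort_values(["specimen", "condition"]).reset_index(drop=True)

    scalar_tests = _scalar_tests(per_condition, alpha)
    regional_tests = _regional_tests(regional, alpha)

    return StudyReport(
        per_condition=per_condition,
        regional=regional,
        scalar_tests=scalar_tests,
        regional_tests=regional_tests,
        table1=_contact_table(per_condition, scalar_tests),
        table2=_regional_table(regional, regional_tests),
        table3=_pose_table(per_condition, scalar_tests),
        qc=qc,
        alpha=alpha,
    )


def _paired_frames(df: pd.DataFrame, flexion: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    sub = df[df["flexion"] == flexion]
    a = sub[sub["ccl_status"] == "transected"].set_index("specimen").sort_index()
    b = sub[sub["ccl_status"] == "intact"].set_index("specimen").sort_index()
    if not a.index.equals(b.index):
        raise MissingDataError(
            f"intact/transected specimens do not match at {flexion} deg"
        )
    return a, b


def _scalar_tests(per_condition: pd.DataFrame, alpha: float) -> pd.DataFrame:
    out = []
    for flexion in FLEXION_LABELS:
        trans, intact = _paired_frames(per_condition, flexion)
        for metric in SCALAR_METRICS:
            sample = st.PairedSample(
                tuple(trans.index),
                trans[metric].to_numpy(),
                intact[metric].to_numpy(),
            )
            r = st.paired_t(sample)
            out.append(
                {
                    "flexion": flexion,
                    "metric": metric,
                    "mean_intact": float(intact[metric].mean()),
                    "sd_intact": float(intact[metric].std(ddof=1)),
                    "mean_transected": float(trans[metric].mean()),
                    "sd_transected": float(trans[metric].std(ddof=1)),
                    "mean_diff": r.mean_diff,
                    "t": r.t,
                    "df": r.df,
                    "p": r.p,
                    "significant": r.p < alpha,
                }
            )
    return pd.DataFrame(out)


def _regional_tests(regional: pd.DataFrame, alpha: float) -> pd.DataFrame:
    out = []
    for flexion in FLEXION_LABELS:
        sub = regional[regional["flexion"] == flexion]
        res = st.regional_glm(
            sub[["specimen", "compartment", "region", "ccl_status", "force"]],
            alpha=alpha,
        )
        res.insert(0, "flexion", flexion)
        out.append(res)
    return pd.concat(out, ignore_index=True)


def _condition_summary(
    df: pd.DataFrame, value: str
) -> dict[str, float]:
    cells = {}
    for flexion in FLEXION_LABELS:
        for status in STATUS_LEVELS:
            vals = df[(df["flexion"] == flexion) & (df["ccl_status"] == status)][value]
            mean, sd = st.summarize(vals)
            cells[f"mean_{flexion}_{status}"] = mean
            cells[f"sd_{flexion}_{status}"] = sd
    return cells


def _contact_table(per_condition: pd.DataFrame, scalar_tests: pd.DataFrame) -> pd.DataFrame:
    sig = scalar_tests.set_index(["metric", "flexion"])["significant"]
    rows = []
    for metric, compartment, column in [
        ("contact_area_mm2", "total", "area_total"),
        ("contact_area_mm2", "medial", "area_medial"),
        ("contact_area_mm2", "lateral", "area_lateral"),
        ("peak_pressure_mpa", "medial", "peak_medial"),
        ("peak_pressure_mpa", "lateral", "peak_lateral"),
        ("mean_pressure_mpa", "total", "mean_total"),
        ("mean_pressure_mpa", "medial", "mean_medial"),
        ("mean_pressure_mpa", "lateral", "mean_lateral"),
        ("peak_location_pct", "medial", "loc_medial"),
        ("peak_location_pct", "lateral", "loc_lateral"),
    ]:
        scale = 100.0 if metric == "peak_location_pct" else 1.0
        row = {"metric": metric, "compartment": compartment}
        cells = _condition_summary(per_condition, column)
        row.update({k: v * scale for k, v in cells.items()})
        for flexion in FLEXION_LABELS:
            row[f"significant_{flexion}"] = bool(sig.loc[(column, flexion)])
        rows.append(row)
    return pd.DataFrame(rows)


def _regional_table(regional: pd.DataFrame, regional_tests: pd.DataFrame) -> pd.DataFrame:
    sig = regional_tests.set_index(["compartment", "region", "flexion"])["significant"]
    rows = []
    for compartment in ("medial", "lateral"):
        for region in ct.REGIONS:
            sub = regional[
                (regional["compartment"] == compartment) & (regional["region"] == region)
            ].rename(columns={"force": "value"})
            row = {"compartment": compartment, "region": region}
            row.update(_condition_summary(sub, "value"))
            for flexion in FLEXION_LABELS:
                row[f"significant_{flexion}"] = bool(sig.loc[(compartment, region, flexion)])
            rows.append(row)
    return pd.DataFrame(rows)


def _pose_table(per_condition: pd.DataFrame, scalar_tests: pd.DataFrame) -> pd.DataFrame:
    sig = scalar_tests.set_index(["metric", "flexion"])["significant"]
    rows = []
    for metric in JcsPose.FIELDS:
        row = {"component": metric}
        row.update(_condition_summary(per_condition, metric))
        for flexion in FLEXION_LABELS:
            row[f"significant_{flexion}"] = bool(sig.loc[(metric, flexion)])
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(config: StudyConfig) -> StudyReport:
    """Load inputs, analyze, and (when an output dir is configured) persist
    the per-specimen intermediates, summary tables and QC report."""
    records = load_study_inputs(config.input_dir)
    report = analyze_records(records, alpha=config.alpha, threshold=config.threshold)
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report


# ---------------------------------------------------------------------------
# reference significance pattern
# ---------------------------------------------------------------------------

#: contact cells that the CCL-transection caudal-shift effect is expected to
#: flag at the stance-phase angle (and to leave unflagged in high flexion)
PATTERN_SCALARS = ("area_medial", "peak_medial", "loc_medial")


def significance_flags(report: StudyReport) -> dict[str, bool]:
    """Flatten the report's significance flags into ``{cell: bool}``."""
    flags = {}
    for r in report.scalar_tests.itertuples():
        flags[f"{r.metric}@{r.flexion}"] = bool(r.significant)
    for r in report.regional_tests.itertuples():
        flags[f"force_{r.compartment}_{r.region}@{r.flexion}"] = bool(r.significant)
    return flags


def matches_caudal_shift_pattern(report: StudyReport) -> bool:
    """Whether a study run reproduces the expected effect pattern: medial
    contact area, medial peak pressure, medial peak location and all six
    regional forces significantly altered at the stance-phase angle, with
    none of those same cells significant in high flexion."""
    flags = significance_flags(report)
    cells = list(PATTERN_SCALARS) + [
        f"force_{c}_{r}" for c in ("medial", "lateral") for r in ct.REGIONS
    ]
    at_135 = all(flags[f"{cell}@135"] for cell in cells)
    at_90 = not any(flags[f"{cell}@90"] for cell in cells)
    return at_135 and at_90


def export_heatmap(pmap, path: str | Path) -> None:
    """Convenience PNG heat-map export of one pressure map (caudal at the
    bottom)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(2.4, 4.8))
    im = ax.imshow(pmap.pressures, origin="lower", cmap="inferno", aspect="auto")
    ax.set_xlabel("mediolateral sensel")
    ax.set_ylabel("craniocaudal sensel (caudal at bottom)")
    ax.set_title(f"{pmap.compartment} compartment")
    fig.colorbar(im, ax=ax, label="pressure (MPa)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
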