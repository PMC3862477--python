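"""Femorotibial contact metrics from thin-film pressure-sensor grids.

A :class:`PressureMap` is the per-compartment sensel grid recorded by a
thin-film pressure measurement system (sensing area 30.9 mm x 12.0 mm,
sensitivity 0.01 MPa, range 0.5-30.0 MPa).  Rows run craniocaudally with
row 0 the caudal-most row; columns run mediolaterally.  From each map the
module computes:

* contact area (mm^2): in-contact sensel count times sensel area, where a
  sensel is in contact iff its pressure is at or above the threshold
  (default: the sensor sensitivity);
* peak and mean contact pressure (MPa), both over the contact area only;
* peak-pressure location: sagittal distance from the peak sensel to the
  digitized caudal margin of the tibial condyle divided by the condyle
  length, a dimensionless fraction (0 = caudal margin, 1 = cranial margin);
* regional contact forces (N): the condyle span split into three equal
  bands (cranial, central, caudal), force per band = sum of pressure times
  sensel area (MPa * mm^2 = N);
* medial-to-lateral force ratio with the 50:50 +/- 10% balance predicate
  used when seating the specimen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InputError, NoContactError

__all__ = [
    "PressureMap",
    "CondyleMargins",
    "ContactMetrics",
    "contact_mask",
    "contact_area",
    "peak_pressure",
    "mean_pressure",
    "peak_pressure_location",
    "regional_forces",
    "mediolateral_ratio",
    "is_balanced",
    "compartment_metrics",
    "joint_totals",
]

logger = logging.getLogger(__name__)

REGIONS = ("cranial", "central", "caudal")

DEFAULT_SATURATION_MPA = 30.0
DEFAULT_SENSITIVITY_MPA = 0.01


@dataclass(frozen=True)
class PressureMap:
    """One compartment's sensel grid, MPa, row 0 = caudal-most row."""

    compartment: str
    pressures: np.ndarray
    row_pitch: float
    col_pitch: float
    saturation: float = DEFAULT_SATURATION_MPA
    sensitivity: float = DEFAULT_SENSITIVITY_MPA

    def __post_init__(self):
        if self.compartment not in ("medial", "lateral"):
            raise InputError(f"compartment must be medial|lateral, got {self.compartment!r}")
        p = np.asarray(self.pressures, dtype=float)
        if p.ndim != 2 or p.size == 0:
            raise InputError(f"pressures must be a non-empty 2-D grid, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise InputError("pressure grid contains non-finite values")
        if p.min() < 0:
            raise InputError(f"negative pressure {p.min()} MPa in grid")
        if p.max() > self.saturation + 1e-12:
            raise InputError(
                f"pressure {p.max()} MPa exceeds saturation {self.saturation} MPa"
            )
        if not (self.row_pitch > 0 and self.col_pitch > 0):
            raise InputError("sensel pitches must be positive")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "pressures", p)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pressures.shape

    @property
    def sensel_area(self) -> float:
        """Area of one sensel, mm^2."""
        return self.row_pitch * self.col_pitch

    @property
    def n_saturated(self) -> int:
        """QC counter: sensels pinned at the saturation pressure."""
        return int(np.sum(self.pressures >= self.saturation))


@dataclass(frozen=True)
class CondyleMargins:
    """Digitized caudal and cranial margins of the tibial condyle, as
    fractional row coordinates in sensel-center units (row 0 = caudal)."""

    caudal_row: float
    cranial_row: float

    def __post_init__(self):
        if not (self.cranial_row > self.caudal_row):
            raise InputError(
                f"cranial margin ({self.cranial_row}) must be cranial to the "
                f"caudal margin ({self.caudal_row})"
            )

    @property
    def span(self) -> float:
        """Condyle length in row units."""
        return self.cranial_row - self.caudal_row

    def check_within(self, pmap: PressureMap) -> None:
        n_rows = pmap.shape[0]
        if self.caudal_row < -0.5 or self.cranial_row > n_rows - 0.5:
            raise InputError(
                f"margins ({self.caudal_row}, {self.cranial_row}) exceed the "
                f"grid extent of {n_rows} rows"
            )


@dataclass(frozen=True)
class ContactMetrics:
    """All per-compartment contact quantities for one loading condition."""

    compartment: str
    area: float  # mm^2
    peak_pressure: float  # MPa
    mean_pressure: float  # MPa
    peak_location: float  # fraction of condyle length from the caudal margin
    forces: Mapping[str, float]  # N, keys cranial/central/caudal
    total_force: float  # N
    n_saturated: int = 0

    def __post_init__(self):
        object.__setattr__(self, "forces", dict(self.forces))
        if set(self.forces) != set(REGIONS):
            raise InputError(f"forces must have keys {REGIONS}")
        if abs(sum(self.forces.values()) - self.total_force) > 1e-9 * max(
            1.0, abs(self.total_force)
        ):
            raise InputError("regional forces do not sum to the total force")
        if not (0.0 <= self.peak_location <= 1.0):
            raise InputError(f"peak_location {self.peak_location} outside [0, 1]")
        if self.mean_pressure > self.peak_pressure + 1e-12:
            raise InputError("mean pressure exceeds peak pressure")


def _threshold(pmap: PressureMap, threshold: float | None) -> float:
    thr = pmap.sensitivity if threshold is None else float(threshold)
    if thr < 0:
        raise InputError(f"threshold must be >= 0, got {thr}")
    return thr


def contact_mask(pmap: PressureMap, threshold: float | None = None) -> np.ndarray:
    """Boolean grid: sensel in contact iff pressure >= threshold (default:
    the sensor sensitivity, 0.01 MPa)."""
    return pmap.pressures >= _threshold(pmap, threshold)


def contact_area(pmap: PressureMap, threshold: float | None = None) -> float:
    """Contact area in mm^2: in-contact sensel count x sensel area."""
    return float(np.count_nonzero(contact_mask(pmap, threshold))) * pmap.sensel_area


def peak_pressure(
    pmap: PressureMap, threshold: float | None = None
) -> tuple[float, tuple[int, int]]:
    """Highest pressure in the contact area and its sensel index.

    Ties are broken deterministically toward the most caudal row (lowest row
    index), then the lowest column.
    """
    mask = contact_mask(pmap, threshold)
    if not mask.any():
        raise NoContactError(f"no sensel in contact on the {pmap.compartment} map")
    # row-major argmax realises the caudal-most-row-then-lowest-column rule
    flat = np.where(mask, pmap.pressures, -np.inf)
    idx = int(np.argmax(flat))
    r, c = divmod(idx, pmap.shape[1])
    return float(pmap.pressures[r, c]), (r, c)


def mean_pressure(pmap: PressureMap, threshold: float | None = None) -> float:
    """Arithmetic mean pressure over the in-contact sensels only, MPa."""
    mask = contact_mask(pmap, threshold)
    if not mask.any():
        raise NoContactError(f"no sensel in contact on the {pmap.compartment} map")
    return float(pmap.pressures[mask].mean())


def peak_pressure_location(
    pmap: PressureMap,
    margins: CondyleMargins,
    threshold: float | None = None,
) -> float:
    """Sagittal peak-pressure location as a fraction of condyle length.

    ``(peak_row - caudal_margin) / (cranial_margin - caudal_margin)``,
    clamped to [0, 1] with a logged warning if the peak falls outside the
    digitized margins.
    """
    margins.check_within(pmap)
    _, (r, _) = peak_pressure(pmap, threshold)
    frac = (r - margins.caudal_row) / margins.span
    if frac < 0.0 or frac > 1.0:
        logger.warning(
            "%s peak at row %d lies outside the condyle margins "
            "(%.2f, %.2f); clamping location %.3f to [0, 1]",
            pmap.compartment, r, margins.caudal_row, margins.cranial_row, frac,
        )
        frac = min(1.0, max(0.0, frac))
    return float(frac)


def _band_index(rows: np.ndarray, margins: CondyleMargins, compartment: str) -> np.ndarray:
    """Assign row-center coordinates to bands 0 (caudal) .. 2 (cranial)."""
    u = (rows - margins.caudal_row) / margins.span
    outside = (u < 0.0) | (u > 1.0)
    if outside.any():
        logger.warning(
            "%s map: %d in-contact sensel rows outside the condyle margins; "
            "clamping to the terminal bands", compartment, int(outside.sum()),
        )
    return np.clip(np.floor(u * 3.0).astype(int), 0, 2)


def regional_forces(
    pmap: PressureMap,
    margins: CondyleMargins,
    threshold: float | None = None,
) -> dict[str, float]:
    """Contact force (N) in the cranial, central and caudal thirds of the
    condyle span.

    The margin-to-margin span is split into three equal-length bands and
    every in-contact sensel is assigned by its row-center coordinate;
    sensels outside the span are clamped to the nearest terminal band (with
    a logged warning) so that no force is silently dropped.
    """
    margins.check_within(pmap)
    mask = contact_mask(pmap, threshold)
    forces = {region: 0.0 for region in REGIONS}
    if mask.any():
        rows, _ = np.nonzero(mask)
        band = _band_index(rows.astype(float), margins, pmap.compartment)
        contrib = pmap.pressures[mask] * pmap.sensel_area
        for b, region in enumerate(("caudal", "central", "cranial")):
            forces[region] = float(contrib[band == b].sum())
    return forces


def mediolateral_ratio(
    medial: PressureMap, lateral: PressureMap, threshold: float | None = None
) -> float:
    """Medial share of the total femorotibial contact force."""
    if medial.compartment != "medial" or lateral.compartment != "lateral":
        raise InputError("mediolateral_ratio expects a (medial, lateral) map pair")

    def _force(pmap: PressureMap) -> float:
        mask = contact_mask(pmap, threshold)
        return float(pmap.pressures[mask].sum()) * pmap.sensel_area

    f_med, f_lat = _force(medial), _force(lateral)
    if f_med + f_lat == 0.0:
        raise NoContactError("no contact on either compartment")
    return f_med / (f_med + f_lat)


def is_balanced(ratio: float, target: float = 0.5, tol: float = 0.1) -> bool:
    """Whether a medial-to-lateral force ratio satisfies the 50:50 +/- 10%
    seating criterion applied to the intact stifle."""
    return abs(ratio - target) <= tol


def compartment_metrics(
    pmap: PressureMap,
    margins: CondyleMargins,
    threshold: float | None = None,
) -> ContactMetrics:
    """Bundle every contact metric of one compartment map.

    ``total_force`` is the sum of the three regional forces (identical
    summands, so force conservation is exact by construction).
    """
    forces = regional_forces(pmap, margins, threshold)
    peak, _ = peak_pressure(pmap, threshold)
    return ContactMetrics(
        compartment=pmap.compartment,
        area=contact_area(pmap, threshold),
        peak_pressure=peak,
        mean_pressure=mean_pressure(pmap, threshold),
        peak_location=peak_pressure_location(pmap, margins, threshold),
        forces=forces,
        total_force=sum(forces.values()),
        n_saturated=pmap.n_saturated,
    )


def joint_totals(medial: ContactMetrics, lateral: ContactMetrics) -> dict[str, float]:
    """Combined (medial + lateral) joint metrics.

    Area and force add across compartments; the joint peak pressure is the
    larger compartment peak; the joint mean pressure is the pressure sum
    over the combined contact area divided by that area, i.e. total force /
    total area.
    """
    area = medial.area + lateral.area
    total_force = medial.total_force + lateral.total_force
    return {
        "area": area,
        "peak_pressure": max(medial.peak_pressure, lateral.peak_pressure),
        "mean_pressure": total_force / area if area > 0 else 0.0,
        "total_force": total_force,
    }
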