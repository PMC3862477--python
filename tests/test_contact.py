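"""Contact metrics against an independent brute-force per-sensel oracle."""

import numpy as np
import pytest

from stiflemech.contact import (
    CondyleMargins,
    PressureMap,
    compartment_metrics,
    contact_area,
    contact_mask,
    is_balanced,
    joint_totals,
    mean_pressure,
    mediolateral_ratio,
    peak_pressure,
    peak_pressure_location,
    regional_forces,
)
from stiflemech.errors import InputError, NoContactError


def make_map(pressures, compartment="medial", row_pitch=30.9 / 26, col_pitch=1.2):
    return PressureMap(
        compartment=compartment,
        pressures=np.asarray(pressures, dtype=float),
        row_pitch=row_pitch,
        col_pitch=col_pitch,
    )


MARGINS = CondyleMargins(1.5, 24.5)


# --- independent oracle: explicit per-sensel loops -------------------------


def oracle_metrics(pmap, margins, threshold):
    rows, cols = pmap.shape
    n = 0
    peak, peak_idx = -1.0, None
    total = 0.0
    forces = {"cranial": 0.0, "central": 0.0, "caudal": 0.0}
    for r in range(rows):
        for c in range(cols):
            p = pmap.pressures[r, c]
            if p < threshold:
                continue
            n += 1
            total += p
            if p > peak:
                peak, peak_idx = p, (r, c)
            u = (r - margins.caudal_row) / (margins.cranial_row - margins.caudal_row)
            band = min(2, max(0, int(np.floor(u * 3.0))))
            forces[["caudal", "central", "cranial"][band]] += p * pmap.sensel_area
    if n == 0:
        return None
    loc = (peak_idx[0] - margins.caudal_row) / (margins.cranial_row - margins.caudal_row)
    return {
        "area": n * pmap.sensel_area,
        "peak": peak,
        "peak_idx": peak_idx,
        "mean": total / n,
        "loc": min(1.0, max(0.0, loc)),
        "forces": forces,
    }


def random_map(rng, shape=(26, 10)):
    kind = rng.integers(0, 3)
    if kind == 0:
        p = rng.uniform(0, 8, shape)
    elif kind == 1:
        p = rng.uniform(0, 8, shape) * (rng.random(shape) < 0.4)
    else:
        p = np.round(rng.uniform(0, 3, shape), 1)
    return make_map(p)


class TestAgainstOracle:
    def test_random_maps_match_brute_force(self, rng):
        for _ in range(200):
            pmap = random_map(rng)
            thr = float(rng.choice([0.01, 0.5, 1.0]))
            ref = oracle_metrics(pmap, MARGINS, thr)
            mask = contact_mask(pmap, thr)
            assert np.array_equal(mask, pmap.pressures >= thr)
            if ref is None:
                with pytest.raises(NoContactError):
                    peak_pressure(pmap, thr)
                assert contact_area(pmap, thr) == 0.0
                continue
            assert contact_area(pmap, thr) == pytest.approx(ref["area"], rel=1e-12)
            value, idx = peak_pressure(pmap, thr)
            assert value == ref["peak"] and idx == ref["peak_idx"]
            assert mean_pressure(pmap, thr) == pytest.approx(ref["mean"], rel=1e-12)
            assert peak_pressure_location(pmap, MARGINS, thr) == pytest.approx(
                ref["loc"], abs=1e-12
            )
            forces = regional_forces(pmap, MARGINS, thr)
            for region in forces:
                assert forces[region] == pytest.approx(ref["forces"][region], rel=1e-12, abs=1e-12)


class TestBasicExamples:
    def test_area_arithmetic(self):
        grid = np.zeros((5, 4))
        grid.flat[:10] = 1.0
        pmap = make_map(grid, row_pitch=1.2, col_pitch=1.2)
        assert contact_area(pmap) == pytest.approx(14.4)

    def test_empty_map(self):
        pmap = make_map(np.zeros((4, 4)))
        assert not contact_mask(pmap).any()
        assert contact_area(pmap) == 0.0
        with pytest.raises(NoContactError):
            mean_pressure(pmap)

    def test_uniform_map_threshold(self):
        pmap = make_map(np.ones((4, 4)))
        assert contact_mask(pmap).all()
        assert mean_pressure(pmap) == pytest.approx(1.0)

    def test_single_sensel_peak(self):
        grid = np.zeros((26, 10))
        grid[4, 3] = 5.6
        value, idx = peak_pressure(make_map(grid))
        assert value == 5.6 and idx == (4, 3)

    def test_peak_tie_breaks_toward_caudal_then_low_column(self):
        pmap = make_map(np.ones((6, 4)))
        _, idx = peak_pressure(pmap)
        assert idx == (0, 0)

    @pytest.mark.parametrize("row,expected", [(2, 0.0), (13, 0.5), (24, 1.0)])
    def test_peak_location_endpoints_and_midpoint(self, row, expected):
        grid = np.zeros((26, 10))
        grid[row, 5] = 3.0
        margins = CondyleMargins(2.0, 24.0)
        assert peak_pressure_location(make_map(grid), margins) == pytest.approx(expected)

    def test_peak_outside_margins_clamped_with_warning(self, caplog):
        grid = np.zeros((26, 10))
        grid[0, 0] = 2.0
        with caplog.at_level("WARNING"):
            loc = peak_pressure_location(make_map(grid), CondyleMargins(1.5, 24.5))
        assert loc == 0.0
        assert any("outside the condyle margins" in m for m in caplog.messages)


class TestRegionalForces:
    def test_uniform_span_gives_equal_thirds(self):
        grid = np.zeros((26, 10))
        grid[3:21, :] = 2.0  # rows 3..20 = three 6-row bands of margins (2.5, 20.5)
        margins = CondyleMargins(2.5, 20.5)
        forces = regional_forces(make_map(grid), margins)
        assert forces["cranial"] == pytest.approx(forces["central"])
        assert forces["central"] == pytest.approx(forces["caudal"])

    def test_all_load_in_caudal_third(self):
        grid = np.zeros((26, 10))
        grid[2:7, :] = 3.0
        pmap = make_map(grid)
        forces = regional_forces(pmap, MARGINS)
        total = float(grid.sum()) * pmap.sensel_area
        assert forces == {"cranial": 0.0, "central": 0.0, "caudal": pytest.approx(total)}

    def test_conservation(self, rng):
        for _ in range(50):
            pmap = random_map(rng)
            m_forces = regional_forces(pmap, MARGINS)
            mask = contact_mask(pmap)
            total = float(pmap.pressures[mask].sum()) * pmap.sensel_area
            assert sum(m_forces.values()) == pytest.approx(total, rel=1e-12)

    def test_translation_equivariance_of_peak_location(self):
        margins = CondyleMargins(2.0, 24.0)
        grid = np.zeros((26, 10))
        grid[8, 4] = 4.0
        base = peak_pressure_location(make_map(grid), margins)
        shifted = np.roll(grid, 3, axis=0)
        out = peak_pressure_location(make_map(shifted), margins)
        assert out - base == pytest.approx(3 / margins.span)

    def test_pressure_scaling(self):
        grid = np.zeros((26, 10))
        grid[5:12, 2:8] = 1.7
        a, b = make_map(grid), make_map(3.0 * grid)
        assert contact_area(b) == contact_area(a)
        assert mean_pressure(b) == pytest.approx(3.0 * mean_pressure(a))
        fa, fb = regional_forces(a, MARGINS), regional_forces(b, MARGINS)
        for region in fa:
            assert fb[region] == pytest.approx(3.0 * fa[region])


class TestMediolateral:
    def test_equal_maps_balanced(self):
        grid = np.ones((26, 10))
        r = mediolateral_ratio(make_map(grid, "medial"), make_map(grid, "lateral"))
        assert r == pytest.approx(0.5)
        assert is_balanced(r)

    def test_lateral_zero_gives_one(self):
        med = make_map(np.ones((26, 10)), "medial")
        lat = make_map(np.zeros((26, 10)), "lateral")
        r = mediolateral_ratio(med, lat)
        assert r == 1.0 and not is_balanced(r)

    def test_random_pair_matches_brute_force(self, rng):
        for _ in range(20):
            med = make_map(rng.uniform(0, 5, (26, 10)), "medial")
            lat = make_map(rng.uniform(0, 5, (26, 10)), "lateral")
            f = lambda m: sum(
                m.pressures[r, c] * m.sensel_area
                for r in range(26)
                for c in range(10)
                if m.pressures[r, c] >= m.sensitivity
            )
            assert mediolateral_ratio(med, lat) == pytest.approx(
                f(med) / (f(med) + f(lat)), rel=1e-12
            )


class TestCompartmentMetrics:
    def test_fields_match_individual_operations(self, rng):
        pmap = random_map(rng)
        while not contact_mask(pmap).any():
            pmap = random_map(rng)
        m = compartment_metrics(pmap, MARGINS)
        assert m.area == contact_area(pmap)
        assert m.peak_pressure == peak_pressure(pmap)[0]
        assert m.mean_pressure == mean_pressure(pmap)
        assert m.peak_location == peak_pressure_location(pmap, MARGINS)
        assert m.forces == regional_forces(pmap, MARGINS)
        assert m.total_force == pytest.approx(sum(m.forces.values()), rel=1e-12)

    def test_joint_totals_combine_compartments(self, rng):
        med = make_map(rng.uniform(0.5, 5, (26, 10)), "medial")
        lat = make_map(rng.uniform(0.5, 5, (26, 10)), "lateral")
        mm = compartment_metrics(med, MARGINS)
        ml = compartment_metrics(lat, MARGINS)
        tot = joint_totals(mm, ml)
        assert tot["area"] == pytest.approx(mm.area + ml.area)
        assert tot["peak_pressure"] == max(mm.peak_pressure, ml.peak_pressure)
        assert tot["total_force"] == pytest.approx(mm.total_force + ml.total_force)

    def test_saturation_counter(self):
        grid = np.zeros((26, 10))
        grid[3, 3] = 30.0
        assert make_map(grid).n_saturated == 1


class TestValidation:
    def test_negative_pressure_rejected(self):
        with pytest.raises(InputError):
            make_map(np.full((3, 3), -1.0))

    def test_above_saturation_rejected(self):
        with pytest.raises(InputError):
            make_map(np.full((3, 3), 31.0))

    def test_margins_order_enforced(self):
        with pytest.raises(InputError):
            CondyleMargins(10.0, 5.0)

    def test_margins_must_fit_grid(self):
        with pytest.raises(InputError):
            CondyleMargins(1.0, 40.0).check_within(make_map(np.ones((26, 10))))
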