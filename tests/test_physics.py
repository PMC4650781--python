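"""Transport model: range-energy law, WET, Bragg curve, columns, scan field."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from braggmap import (BeamSpec, InvalidInputError, JigGeometry, LUCITE, Slab,
                      UnreachableTargetError, WATER, bragg_depth_dose,
                      column_conditions, default_jig, design_jig_steps,
                      dose_peak_depth, energy_from_residual_range,
                      paintings_for_dose, range_from_energy, scan_field_dose,
                      stopping_power, water_equivalent_thickness)

energies = st.floats(min_value=1.0, max_value=250.0)


class TestRangeEnergy:
    def test_power_law_value_in_water(self):
        assert range_from_energy(79.7, WATER) == pytest.approx(5.11, rel=1e-2)

    def test_vanishes_at_zero_energy(self):
        assert range_from_energy(0.0, WATER) == 0.0
        assert range_from_energy(1e-9, WATER) < 1e-9

    def test_negative_energy_rejected(self):
        with pytest.raises(InvalidInputError):
            range_from_energy(-1.0, WATER)
        with pytest.raises(InvalidInputError):
            energy_from_residual_range(-0.1, WATER)

    @pytest.mark.parametrize("energy", [20.0, 79.7, 150.0])
    def test_water_to_lucite_range_ratio(self, energy):
        ratio = range_from_energy(energy, WATER) / range_from_energy(energy, LUCITE)
        assert ratio == pytest.approx(4.8 / 4.1, rel=1e-6)

    @given(energy=energies)
    def test_inverse_round_trip(self, energy):
        back = energy_from_residual_range(range_from_energy(energy, WATER), WATER)
        assert back == pytest.approx(energy, rel=1e-9)

    @given(e1=energies, e2=energies)
    def test_monotone_in_energy(self, e1, e2):
        if e1 < e2:
            assert range_from_energy(e1, WATER) < range_from_energy(e2, WATER)

    def test_known_residual_range_inverts_to_beam_energy(self):
        assert energy_from_residual_range(5.11, WATER) == pytest.approx(79.7, rel=1e-2)


class TestStoppingPower:
    def test_integral_of_inverse_reproduces_range(self):
        # calculus identity: R(E0) = int_0^E0 dE / S(E), with keV/um = 10 MeV/cm
        grid = np.linspace(1e-9, 79.7, 20001)
        inv_s = np.array([1.0 / (10.0 * stopping_power(e, WATER)) for e in grid])
        assert np.trapezoid(inv_s, grid) == pytest.approx(
            range_from_energy(79.7, WATER), rel=1e-3)

    def test_decreases_with_energy(self):
        grid = np.linspace(1.0, 200.0, 50)
        values = [stopping_power(e, WATER) for e in grid]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_entrance_let_scale(self):
        # the 79.7-MeV entrance LET_d in the published column table is 0.9
        assert stopping_power(79.7, WATER) == pytest.approx(0.9, rel=0.2)

    def test_zero_energy_rejected(self):
        with pytest.raises(InvalidInputError):
            stopping_power(0.0, WATER)


class TestWET:
    def test_empty_stack(self):
        assert water_equivalent_thickness([]) == 0.0

    def test_lucite_slab(self):
        assert water_equivalent_thickness([Slab(LUCITE, 1.0)]) == pytest.approx(
            4.8 / 4.1, rel=1e-6)

    def test_three_films(self):
        films = [Slab(LUCITE, 0.0268)] * 3
        assert water_equivalent_thickness(films) == pytest.approx(0.094, rel=0.01)

    @given(th=st.lists(st.floats(min_value=0, max_value=2), min_size=0, max_size=6))
    def test_additivity(self, th):
        slabs = [Slab(LUCITE, t) for t in th]
        total = water_equivalent_thickness(slabs)
        parts = sum(water_equivalent_thickness([s]) for s in slabs)
        assert total == pytest.approx(parts, abs=1e-12)


class TestBraggCurve:
    def test_narrow_beam_peaks_at_analytic_range(self):
        b = BeamSpec(energy_spread_sigma=1e-12, straggling_fraction=0.0)
        grid = np.arange(0.0, 5.5, 0.002)
        prof = bragg_depth_dose(b, WATER, grid)
        assert abs(prof.peak_depth - b.range_water) <= 0.002 + 1e-9

    def test_single_interior_maximum(self, beam):
        prof = bragg_depth_dose(beam)
        i = int(np.argmax(prof.dose))
        assert 0 < i < len(prof.depths) - 1
        assert np.all(np.diff(prof.dose[: i + 1]) > -1e-9)
        tail = prof.dose[i:]
        assert np.all(np.diff(tail[tail > 1e-9]) < 1e-9)

    def test_peak_ratio_decreases_with_energy_spread(self):
        ratios = [bragg_depth_dose(BeamSpec(energy_spread_sigma=s)).peak_to_entrance
                  for s in (0.3, 0.677, 1.2)]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_entrance_letd_matches_stopping_power(self, beam):
        prof = bragg_depth_dose(beam)
        assert prof.let_d[0] == pytest.approx(
            stopping_power(beam.effective_energy, WATER), rel=0.05)

    def test_letd_monotone_through_peak(self, beam):
        prof = bragg_depth_dose(beam)
        live = prof.dose > 1e-3 * prof.dose.max()
        assert np.all(np.diff(prof.let_d[live]) > -1e-6)

    def test_unsorted_grid_rejected(self, beam):
        with pytest.raises(InvalidInputError):
            bragg_depth_dose(beam, WATER, np.array([0.0, 1.0, 0.5]))


class TestColumnConditions:
    def test_normalised_to_column_one(self, conditions):
        assert conditions[0].dose_relative == 1.0

    def test_peak_column_nine_ratio(self, conditions):
        assert conditions[8].dose_relative == pytest.approx(5.5, rel=0.01)
        assert max(c.dose_relative for c in conditions) == conditions[8].dose_relative

    def test_column_one_machine_calibration(self, conditions):
        assert conditions[0].dose_per_painting == pytest.approx(2.6, abs=1e-9)

    def test_letd_strictly_increasing(self, conditions):
        lets = [c.let_d for c in conditions]
        assert all(b > a for a, b in zip(lets, lets[1:]))

    def test_short_range_beam_flags_beyond_range(self, jig):
        weak = BeamSpec(nominal_energy=40.0, effective_energy=40.0)
        cols = column_conditions(weak, jig)  # range ~1.5 cm < distal stacks
        assert any(c.beyond_range for c in cols)
        assert all(c.dose_per_painting == 0.0 for c in cols if c.beyond_range)


class TestJigDesign:
    def test_shallow_target_clamps_to_zero_step(self, beam):
        jig = design_jig_steps(beam, [0.0], kind="depth")
        assert jig.step_thicknesses[0] == 0.0

    def test_increasing_targets_give_monotone_steps(self, beam):
        depths = np.linspace(0.5, 4.9, 12)
        jig = design_jig_steps(beam, list(depths), kind="depth")
        steps = jig.step_thicknesses
        assert all(b >= a for a, b in zip(steps, steps[1:]))

    def test_let_targets_round_trip_through_transport(self, beam):
        targets = [0.9, 1.2, 1.6, 1.8, 1.9, 2.3, 3.0, 5.1, 10.8, 15.2, 17.7, 19.0]
        jig = design_jig_steps(beam, targets, kind="let")
        cols = column_conditions(beam, jig)
        for target, col in zip(targets, cols):
            assert col.let_d == pytest.approx(target, rel=0.10)

    def test_default_jig_fine_steps_near_range_end(self, jig):
        increments = np.diff(jig.step_thicknesses)
        assert increments[0] > increments[-1]
        assert increments[-1] < 0.05  # sub-mm sampling at the distal end

    def test_unreachable_let_raises(self, beam):
        with pytest.raises(UnreachableTargetError):
            design_jig_steps(beam, [500.0], kind="let")

    def test_peak_depth_between_column8_and_column10(self, beam, jig):
        z_peak = dose_peak_depth(beam)
        assert jig.cell_depth_water(8) < z_peak <= jig.cell_depth_water(10)


class TestScanField:
    def test_single_spot_half_maximum_at_half_fwhm(self, beam):
        centre = scan_field_dose(0.0, 0.0, beam, 0)
        half = scan_field_dose(beam.spot_fwhm / 2, 0.0, beam, 0)
        assert half / centre == pytest.approx(0.5, rel=1e-9)

    def test_field_matches_brute_force_sum(self, beam):
        # independent double loop over the 441 spot grid
        sigma = beam.spot_fwhm / (2 * math.sqrt(2 * math.log(2)))
        for x, y in [(0.0, 0.0), (1.3, -0.4), (3.6, 3.6)]:
            brute = sum(
                math.exp(-((x - i) ** 2 + (y - j) ** 2) / (2 * sigma ** 2))
                for i in range(-10, 11) for j in range(-10, 11))
            assert scan_field_dose(x, y, beam, 10) == pytest.approx(brute, rel=1e-12)

    def test_symmetric_and_centre_peaked(self, beam):
        assert scan_field_dose(2.0, -1.0, beam, 10) == pytest.approx(
            scan_field_dose(-2.0, 1.0, beam, 10), rel=1e-12)
        assert scan_field_dose(0.0, 0.0, beam, 10) >= scan_field_dose(5.0, 5.0, beam, 10)

    def test_central_well_span_uniformity(self, beam):
        # the 8 wells of a column span 7.2 cm; published uniformity 99-100%
        y = np.linspace(-3.6, 3.6, 181)
        dose = scan_field_dose(np.zeros_like(y), y, beam, 10)
        assert dose.min() / dose.max() >= 0.99


class TestPaintings:
    def test_zero_target(self, beam):
        assert paintings_for_dose(0.0, beam) == (0, 0.0)

    def test_two_gray_rounding(self, beam):
        n, delivered = paintings_for_dose(2.0, beam)
        assert n == 77
        assert delivered == pytest.approx(2.002, abs=1e-9)

    def test_negative_rejected(self, beam):
        with pytest.raises(InvalidInputError):
            paintings_for_dose(-0.5, beam)


class TestGeometryValidation:
    def test_twelve_columns_required(self):
        with pytest.raises(InvalidInputError):
            JigGeometry(step_thicknesses=(0.0,) * 11)

    def test_decreasing_steps_rejected(self):
        steps = [0.1] * 12
        steps[5] = 0.05
        with pytest.raises(InvalidInputError):
            JigGeometry(step_thicknesses=tuple(steps))

    def test_effective_energy_cannot_exceed_nominal(self):
        with pytest.raises(InvalidInputError):
            BeamSpec(nominal_energy=50.0, effective_energy=60.0)
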