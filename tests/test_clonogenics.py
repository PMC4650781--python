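"""Survival analysis: PE, SF, LOD, LQ fitting, isoeffect doses, RBE, F test."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from braggmap import (InsufficientDataError, InvalidInputError, LQFit,
                      SurvivalPoint, compare_fits_f_test, dose_at_sf, fit_lq,
                      lod_filter, lod_threshold, plating_efficiency, rbe,
                      rbe_let_table, sf_at_dose)
from braggmap.clonogenics import lq_survival

H460_PHOTON = LQFit.from_params(0.290, 0.083, label="photons")
DOSES = (0.0, 0.1, 0.2, 0.5, 1.0, 2.0, 4.0, 6.0)


def poisson_points(alpha, beta, rng, doses=DOSES, wells=16, seeded=100, pe=0.8):
    pts = []
    for d in doses:
        mean = seeded * pe * math.exp(-alpha * d - beta * d * d)
        pts += [SurvivalPoint(d, c / (seeded * pe))
                for c in rng.poisson(mean, wells)]
    return lod_filter(pts, seeded, pe)


class TestPlatingEfficiency:
    def test_uniform_controls(self):
        assert plating_efficiency([85] * 8, 100) == (0.85, 0.0)

    def test_two_control_wells(self):
        pe, sem = plating_efficiency([80, 90], 100)
        assert pe == pytest.approx(0.85)
        assert sem == pytest.approx(0.05)

    def test_poisson_controls_recover_truth(self, rng):
        counts = rng.poisson(80, 16)
        pe, sem = plating_efficiency(counts, 100)
        assert abs(pe - 0.8) <= 3 * max(sem, 1e-6)

    def test_empty_controls_rejected(self):
        with pytest.raises(InvalidInputError):
            plating_efficiency([], 100)


class TestLodFilter:
    def test_threshold_formula(self):
        assert lod_threshold(100, 0.8) == pytest.approx(0.0125, abs=1e-15)

    def test_sub_threshold_dose_level_dropped(self):
        pts = [SurvivalPoint(0.0, 1.0), SurvivalPoint(2.0, 0.2),
               SurvivalPoint(6.0, 0.01)]
        kept = lod_filter(pts, 100, 0.8)
        assert [p.dose for p in kept] == [0.0, 2.0]

    def test_point_exactly_at_threshold_retained(self):
        pts = [SurvivalPoint(0.0, 1.0), SurvivalPoint(4.0, 0.0125)]
        assert len(lod_filter(pts, 100, 0.8)) == 2

    def test_all_above_threshold_unchanged(self):
        pts = [SurvivalPoint(d, 0.5) for d in (0.0, 1.0, 2.0)]
        assert lod_filter(pts, 100, 0.8) == pts

    def test_zero_dose_survives_filtering(self, rng):
        pts = poisson_points(0.883, 0.956, rng)
        assert 0.0 in {p.dose for p in pts}

    def test_aggregate_decides_per_dose_level(self):
        # one empty well must not drop a dose level whose aggregate is fine
        pts = [SurvivalPoint(0.0, 1.0)] * 4 + [SurvivalPoint(2.0, 0.0)]
        pts += [SurvivalPoint(2.0, 0.5)] * 3
        kept = lod_filter(pts, 100, 0.8)
        assert sum(p.dose == 2.0 for p in kept) == 4


class TestLqFit:
    def test_noiseless_exact_recovery(self):
        pts = [SurvivalPoint(d, math.exp(-0.2 * d - 0.05 * d * d))
               for d in range(7)]
        fit = fit_lq(pts)
        assert fit.alpha == pytest.approx(0.2, abs=1e-6)
        assert fit.beta == pytest.approx(0.05, abs=1e-6)

    @given(alpha=st.floats(min_value=0.0, max_value=1.0),
           beta=st.floats(min_value=0.0, max_value=1.0))
    def test_noiseless_recovery_over_parameter_plane(self, alpha, beta):
        pts = [SurvivalPoint(d, math.exp(-alpha * d - beta * d * d))
               for d in (0.0, 0.5, 1.0, 2.0, 3.0)]
        fit = fit_lq(pts)
        assert fit.alpha == pytest.approx(alpha, abs=1e-6)
        assert fit.beta == pytest.approx(beta, abs=1e-6)

    def test_poisson_experiment_recovers_within_two_se(self, rng):
        fit = fit_lq(poisson_points(0.268, 0.097, rng))
        assert abs(fit.alpha - 0.268) <= 2 * fit.se_alpha
        assert abs(fit.beta - 0.097) <= 2 * fit.se_beta

    def test_agrees_with_brute_force_grid_search(self, rng):
        pts = poisson_points(0.268, 0.097, rng, doses=(0.0, 1.0, 2.0, 4.0),
                             wells=8)
        fit = fit_lq(pts, reweight_iterations=0)
        dose = np.array([p.dose for p in pts])
        sf = np.array([p.sf for p in pts])
        floor = sf[sf > 0].min()
        w = 1.0 / np.maximum(sf, floor)
        grid_a = np.linspace(0.0, 0.8, 161)
        grid_b = np.linspace(0.0, 0.4, 161)
        ss = np.array([[np.sum(w * (sf - lq_survival(dose, a, b)) ** 2)
                        for b in grid_b] for a in grid_a])
        ia, ib = np.unravel_index(np.argmin(ss), ss.shape)
        assert fit.alpha == pytest.approx(grid_a[ia], abs=grid_a[1] - grid_a[0])
        assert fit.beta == pytest.approx(grid_b[ib], abs=grid_b[1] - grid_b[0])

    def test_insufficient_dose_levels_rejected(self):
        pts = [SurvivalPoint(0.0, 1.0), SurvivalPoint(2.0, 0.3)]
        with pytest.raises(InsufficientDataError):
            fit_lq(pts)


class TestIsoeffect:
    def test_published_sf2_low_and_high_let(self):
        assert sf_at_dose(LQFit.from_params(0.268, 0.097), 2.0) == pytest.approx(
            0.40, abs=0.005)
        assert sf_at_dose(LQFit.from_params(0.883, 0.956), 2.0) == pytest.approx(
            0.0037, abs=5e-5)

    def test_sf_at_zero_dose_is_one(self):
        assert sf_at_dose(LQFit.from_params(0.7, 0.3), 0.0) == 1.0

    def test_photon_d10(self):
        assert dose_at_sf(H460_PHOTON, 0.10) == pytest.approx(3.80, abs=0.01)

    def test_pure_linear_closed_form(self):
        fit = LQFit.from_params(math.log(2.0), 0.0)
        assert dose_at_sf(fit, 0.5) == pytest.approx(1.0, rel=1e-12)

    @given(alpha=st.floats(min_value=0.01, max_value=1.5),
           beta=st.floats(min_value=0.0, max_value=1.0),
           sf=st.floats(min_value=1e-4, max_value=0.999))
    def test_mutually_inverse(self, alpha, beta, sf):
        fit = LQFit.from_params(alpha, beta)
        assert sf_at_dose(fit, dose_at_sf(fit, sf)) == pytest.approx(sf, rel=1e-9)

    def test_invalid_survival_levels_rejected(self):
        with pytest.raises(InvalidInputError):
            dose_at_sf(H460_PHOTON, 1.0)
        with pytest.raises(InvalidInputError):
            dose_at_sf(H460_PHOTON, 0.0)


class TestRbe:
    def test_published_high_let_values(self):
        assert rbe(H460_PHOTON, LQFit.from_params(0.883, 0.956)).rbe == (
            pytest.approx(3.28, rel=0.01))
        h1437 = LQFit.from_params(0.050, 0.041)
        assert rbe(h1437, LQFit.from_params(0.180, 0.095)).rbe == (
            pytest.approx(1.70, rel=0.01))

    def test_self_reference_is_unity(self):
        res = rbe(H460_PHOTON, H460_PHOTON, 0.10)
        assert res.rbe == pytest.approx(1.0, rel=1e-12)

    @given(a1=st.floats(min_value=0.05, max_value=1.0),
           b1=st.floats(min_value=0.0, max_value=0.5),
           a2=st.floats(min_value=0.05, max_value=1.0),
           b2=st.floats(min_value=0.0, max_value=0.5))
    def test_reciprocal_under_role_swap(self, a1, b1, a2, b2):
        f1, f2 = LQFit.from_params(a1, b1), LQFit.from_params(a2, b2)
        assert rbe(f1, f2).rbe * rbe(f2, f1).rbe == pytest.approx(1.0, rel=1e-9)

    def test_sd_propagates_fit_uncertainty(self):
        ref = LQFit(alpha=0.290, beta=0.083, se_alpha=0.02, se_beta=0.008,
                    cov_alpha_beta=-1e-4)
        test = LQFit(alpha=0.883, beta=0.956, se_alpha=0.05, se_beta=0.04,
                     cov_alpha_beta=-1.5e-3)
        res = rbe(ref, test)
        assert res.sd > 0
        # larger SEs must not shrink the propagated sd
        wider = LQFit(alpha=0.883, beta=0.956, se_alpha=0.10, se_beta=0.08,
                      cov_alpha_beta=-1.5e-3)
        assert rbe(ref, wider).sd > res.sd

    def test_zero_se_fits_give_zero_sd(self):
        res = rbe(H460_PHOTON, LQFit.from_params(0.5, 0.1))
        assert res.sd == 0.0


class TestFTest:
    def test_identical_datasets_give_null_result(self, rng):
        pts = poisson_points(0.268, 0.097, rng)
        f_stat, p = compare_fits_f_test(pts, list(pts))
        assert f_stat == pytest.approx(0.0, abs=1e-6)
        assert p > 0.999

    def test_low_vs_high_let_strongly_separated(self, rng):
        low = poisson_points(0.268, 0.097, rng)
        high = poisson_points(0.883, 0.956, rng)
        _, p = compare_fits_f_test(low, high)
        assert p < 1e-4


class TestRbeTable:
    def test_reference_only_row_is_unity(self):
        table = rbe_let_table({0.3: H460_PHOTON}, H460_PHOTON)
        assert table["rbe"].iloc[0] == pytest.approx(1.0)

    def test_published_parameters_reproduce_published_rbe(self):
        fits = {15.2: LQFit.from_params(0.446, 0.341),
                19.0: LQFit.from_params(0.883, 0.956)}
        table = rbe_let_table(fits, H460_PHOTON)
        assert table["rbe"].tolist() == pytest.approx([1.87, 3.28], rel=0.01)

    def test_undefined_isoeffect_flagged_not_dropped(self):
        fits = {1.0: LQFit.from_params(0.5, 0.1),
                2.0: LQFit.from_params(0.0, 0.0)}
        table = rbe_let_table(fits, H460_PHOTON)
        assert len(table) == 2
        assert np.isnan(table.set_index("let_keV_um").loc[2.0, "rbe"])
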