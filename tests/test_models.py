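"""Closed-form model layer: free energies, fractions, signals, profiles."""

import math

import numpy as np
import pytest

from lemfold import (
    Conditions,
    PopulationProfile,
    R_KCAL,
    ThermalParams,
    ThreeStateParams,
    TwoStateParams,
    gibbs_at,
    midpoint,
    population_profile,
    thermal_fraction_unfolded,
    thermal_signal,
    three_state_fractions,
    three_state_signal,
    two_state_fractions,
    two_state_signal,
)


class TestGibbsAndMidpoint:
    @pytest.mark.parametrize(
        "dg0, m, c, expected",
        [
            (4.32, 0.8, 0.0, 4.32),  # zero-denaturant identity
            (7.7, 2.3, 0.0, 7.7),
            (4.7, 1.7, 2.25, 0.875),  # 4.7 - 1.7*2.25 by hand
        ],
    )
    def test_linear_extrapolation(self, dg0, m, c, expected):
        assert gibbs_at(dg0, m, c) == pytest.approx(expected, abs=1e-12)

    def test_gibbs_vectorized(self):
        c = np.array([0.0, 1.0, 2.0])
        np.testing.assert_allclose(gibbs_at(3.0, 1.5, c), [3.0, 1.5, 0.0])

    @pytest.mark.parametrize(
        "dg0, m, expected",
        [
            (1.5, 0.9, 1.7),  # AAR GdnHCl CD N->I midpoint, printed to 1 decimal
            (4.3, 1.4, 3.1),  # AAR GdnHCl CD N->U midpoint
            (0.0, 2.0, 0.0),
        ],
    )
    def test_midpoint_rounds_to_reference(self, dg0, m, expected):
        assert round(midpoint(dg0, m), 1) == expected

    def test_midpoint_zero_slope_rejected(self):
        with pytest.raises(ZeroDivisionError):
            midpoint(1.0, 0.0)


class TestTwoState:
    def test_half_unfolded_at_midpoint(self, cond):
        p = TwoStateParams(dG0=3.44, m=0.8)
        _, f_u = two_state_fractions(p, p.Dm, cond)
        assert f_u == pytest.approx(0.5, abs=1e-12)

    def test_native_fraction_in_water(self, cond):
        # exp(-4.32/RT)/(1+exp(-4.32/RT)) at 25 degC
        p = TwoStateParams(dG0=4.32, m=0.8)
        _, f_u = two_state_fractions(p, 0.0, cond)
        assert f_u == pytest.approx(6.80e-4, rel=1e-2)

    def test_saturation_limits(self, cond):
        p = TwoStateParams(dG0=4.32, m=0.8)
        f_n_lo, f_u_lo = two_state_fractions(p, 0.0, Conditions(temperature=1e-3))
        assert f_n_lo == pytest.approx(1.0, abs=1e-300)
        assert f_u_lo == pytest.approx(0.0, abs=1e-300)
        _, f_u_hi = two_state_fractions(p, 1e6, cond)
        assert f_u_hi == pytest.approx(1.0, abs=1e-12)

    def test_unfolded_fraction_monotone_in_denaturant(self, cond):
        p = TwoStateParams(dG0=5.0, m=1.3)
        grid = np.linspace(0, 12, 500)
        _, f_u = two_state_fractions(p, grid, cond)
        assert np.all(np.diff(f_u) >= 0)

    def test_signal_midpoint_of_unit_amplitude(self, cond):
        p = TwoStateParams(dG0=3.2, m=0.8, a1=1.0, b1=0.0, c1=0.0, p1=0.0)
        assert two_state_signal(p, p.Dm, cond) == pytest.approx(0.5, abs=1e-12)

    def test_signal_in_water_tracks_native_baseline(self, cond):
        p = TwoStateParams(dG0=4.32, m=0.8, a1=1.0, b1=0.0, c1=0.0, p1=0.0)
        assert two_state_signal(p, 0.0, cond) == pytest.approx(0.99932, abs=5e-5)

    def test_signal_matches_stepwise_composition(self, cond):
        # independent scalar composition of the LEM chain with math.exp
        p = TwoStateParams(dG0=3.7, m=1.1, a1=0.9, b1=-0.01, c1=0.2, p1=0.02)
        for c in (0.0, 1.7, 3.36, 5.5, 8.0):
            k = math.exp(-(p.dG0 - p.m * c) / cond.rt)
            f_u = k / (1 + k)
            expected = (p.a1 + p.b1 * c) * (1 - f_u) + (p.c1 + p.p1 * c) * f_u
            assert two_state_signal(p, c, cond) == pytest.approx(expected, rel=1e-12)


class TestThreeState:
    def test_fractions_at_gdnhcl_2p25(self, gdnhcl_fluor_params, cond):
        """The fluorescence-row parameters put ~60% intermediate at 2.25 M."""
        f_n, f_i, f_u = three_state_fractions(gdnhcl_fluor_params, 2.25, cond)
        assert f_n == pytest.approx(0.313, abs=5e-4)
        assert f_i == pytest.approx(0.615, abs=5e-4)
        assert f_u == pytest.approx(0.072, abs=5e-4)

    def test_fully_native_limit(self, cond):
        p = ThreeStateParams(dG_NI0=25.0, m_NI=0.5, dG_NU0=28.0, m_NU=0.9)
        f_n, f_i, f_u = three_state_fractions(p, 0.0, cond)
        assert f_n == pytest.approx(1.0, abs=1e-12)
        assert f_i == pytest.approx(0.0, abs=1e-12)

    def test_intermediate_fraction_in_water(self, gdnhcl_fluor_params, cond):
        _, f_i, _ = three_state_fractions(gdnhcl_fluor_params, 0.0, cond)
        assert f_i == pytest.approx(0.086, abs=5e-4)

    def test_normalization_everywhere(self, gdnhcl_fluor_params, cond):
        grid = np.concatenate([np.linspace(0, 6, 121), [50.0, 500.0]])
        f_n, f_i, f_u = three_state_fractions(gdnhcl_fluor_params, grid, cond)
        np.testing.assert_allclose(f_n + f_i + f_u, 1.0, atol=1e-12)
        for f in (f_n, f_i, f_u):
            assert np.all((f >= 0) & (f <= 1))

    def test_signal_composes_fractions_and_baselines(self, cond):
        p = ThreeStateParams(
            dG_NI0=1.4, m_NI=0.8, dG_NU0=4.7, m_NU=1.7,
            a1=1.0, b1=0.0, c1=0.6, p1=0.0, e1=0.0, g1=0.0,
        )
        # 0.313*1 + 0.615*0.6 + 0.072*0 at 2.25 M
        assert three_state_signal(p, 2.25, cond) == pytest.approx(0.682, abs=1e-3)

    def test_degenerate_limit_reduces_to_two_state(self, cond):
        """With the intermediate never populated the models agree to 1e-9."""
        p3 = ThreeStateParams(
            dG_NI0=50.0, m_NI=0.1, dG_NU0=50.0, m_NU=10.0,
            a1=1.0, b1=-0.01, c1=123.0, p1=-4.0, e1=0.1, g1=0.02,
        )
        p2 = TwoStateParams(dG0=50.0, m=10.0, a1=1.0, b1=-0.01, c1=0.1, p1=0.02)
        c = np.linspace(0, 8, 161)
        np.testing.assert_allclose(
            three_state_signal(p3, c, cond), two_state_signal(p2, c, cond), atol=1e-9
        )

    def test_additivity_accessors(self, gdnhcl_cd_params):
        p = gdnhcl_cd_params
        assert p.dG_IU0 == pytest.approx(p.dG_NU0 - p.dG_NI0, abs=1e-15)
        assert p.m_IU == pytest.approx(p.m_NU - p.m_NI, abs=1e-15)
        assert p.Dm_NI * p.m_NI == pytest.approx(p.dG_NI0, rel=1e-15)
        assert p.Dm_NU * p.m_NU == pytest.approx(p.dG_NU0, rel=1e-15)

    def test_ordering_constraint_enforced(self):
        with pytest.raises(ValueError, match="dG_NU0"):
            ThreeStateParams(dG_NI0=5.0, m_NI=1.0, dG_NU0=3.0, m_NU=1.5)


class TestThermal:
    def test_half_unfolded_at_tm(self):
        p = ThermalParams(Tm=316.45, dH_vH=70.0, a1=1.0, b1=0.0, c1=0.0, p1=0.0)
        assert thermal_fraction_unfolded(p, p.Tm) == pytest.approx(0.5, abs=1e-12)
        assert thermal_signal(p, p.Tm) == pytest.approx(0.5, abs=1e-12)

    def test_cold_limit_on_native_baseline(self):
        p = ThermalParams(Tm=316.45, dH_vH=70.0, a1=1.0, b1=0.0, c1=0.0, p1=0.0)
        assert thermal_signal(p, 200.0) == pytest.approx(1.0, abs=1e-6)

    def test_fraction_matches_vant_hoff_formula(self):
        p = ThermalParams(Tm=316.45, dH_vH=70.0)
        t = 306.45
        k = math.exp(-70.0 * (1 - t / 316.45) / (R_KCAL * t))
        assert thermal_fraction_unfolded(p, t) == pytest.approx(k / (1 + k), rel=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ThermalParams(Tm=-5.0, dH_vH=70.0)
        with pytest.raises(ValueError):
            ThermalParams(Tm=316.0, dH_vH=0.0)
        with pytest.raises(ValueError):
            thermal_fraction_unfolded(ThermalParams(Tm=316.0, dH_vH=70.0), -1.0)


class TestPopulationProfile:
    def test_single_point_matches_fractions(self, gdnhcl_fluor_params, cond):
        prof = population_profile(gdnhcl_fluor_params, [2.25], cond)
        f = three_state_fractions(gdnhcl_fluor_params, 2.25, cond)
        assert (prof.f_N[0], prof.f_I[0], prof.f_U[0]) == pytest.approx(f, abs=1e-15)
        assert prof.argmax_I == 2.25

    def test_profile_matches_pointwise_scan(self, gdnhcl_cd_params, cond):
        grid = np.arange(0, 6.001, 0.05)
        prof = population_profile(gdnhcl_cd_params, grid, cond)
        scan = np.array(
            [three_state_fractions(gdnhcl_cd_params, c, cond)[1] for c in grid]
        )
        np.testing.assert_allclose(prof.f_I, scan, atol=1e-14)
        assert prof.max_f_I == pytest.approx(scan.max(), abs=1e-14)
        assert prof.argmax_I == grid[scan.argmax()]

    def test_two_state_profile_has_no_intermediate(self, urea_cd_truth, cond):
        prof = population_profile(urea_cd_truth, np.linspace(0, 8, 33), cond)
        assert isinstance(prof, PopulationProfile)
        np.testing.assert_array_equal(prof.f_I, 0.0)
        assert prof.argmax_I is None
        np.testing.assert_allclose(prof.f_N + prof.f_U, 1.0, atol=1e-12)

    def test_grid_validation(self, gdnhcl_cd_params, cond):
        with pytest.raises(ValueError):
            population_profile(gdnhcl_cd_params, [], cond)
        with pytest.raises(ValueError):
            population_profile(gdnhcl_cd_params, [-1.0, 2.0], cond)


def test_parameter_validation():
    with pytest.raises(ValueError):
        TwoStateParams(dG0=4.0, m=0.0)
    with pytest.raises(ValueError):
        ThreeStateParams(dG_NI0=1.0, m_NI=-0.5, dG_NU0=4.0, m_NU=1.0)
    with pytest.raises(ValueError):
        Conditions(temperature=0.0)
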