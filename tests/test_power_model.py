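"""Closed-form model equations: Lambert W numerics, power-duration law,
race times, supplemental power, endurance indices, self-consistency."""

import math

import numpy as np
import pytest
import scipy.special

from _oracles import bisect_wm1
from runpower import (
    AthleteProfile,
    ModelDomainError,
    approx_race_time,
    duration_at_relative_power,
    duration_at_velocity,
    economy_relative_power,
    endurance_summary,
    lambert_w_m1,
    mean_race_velocity,
    p_max,
    race_time,
    relative_power,
    rescaled_coordinates,
    supplemental_factor,
    supplemental_power_rel,
    threshold_intensity,
    verify_self_consistency,
)
from runpower.core import _wm1_series


class TestLambertW:
    def test_branch_point(self):
        assert lambert_w_m1(-1.0 / math.e) == -1.0

    @pytest.mark.parametrize("w", [-1.5, -2.0, -5.0, -10.0, -30.0, -100.0])
    def test_round_trip(self, w):
        assert lambert_w_m1(w * math.exp(w)) == pytest.approx(w, rel=1e-12)

    def test_frozen_value(self):
        # independently obtained by bisection on w*e^w = -0.1
        assert lambert_w_m1(-0.1) == pytest.approx(-3.577152063957, abs=1e-9)

    def test_defining_equation_residual(self):
        z = -np.logspace(-12, np.log10(1 / math.e - 1e-9), 500)
        w = lambert_w_m1(z)
        assert np.all(w <= -1.0)
        assert np.max(np.abs(w * np.exp(w) - z) / np.abs(z)) < 1e-12

    def test_agrees_with_bisection_oracle(self):
        zs = -np.logspace(np.log10(1e-12), np.log10(1 / math.e - 1e-6), 80)
        for z in zs:
            assert lambert_w_m1(float(z)) == pytest.approx(bisect_wm1(float(z)), abs=1e-10)

    def test_agrees_with_scipy(self):
        z = -np.logspace(-10, np.log10(1 / math.e - 1e-8), 200)
        ref = scipy.special.lambertw(z, -1).real
        np.testing.assert_allclose(lambert_w_m1(z), ref, rtol=1e-13, atol=1e-13)

    @pytest.mark.parametrize("z", [0.0, 0.1, -0.5, -1.0, math.nan])
    def test_domain_errors(self, z):
        with pytest.raises(ModelDomainError):
            lambert_w_m1(z)

    def test_series_matches_solver_to_stated_accuracy(self):
        # truncated asymptotic expansion: better than 0.4% on [-0.1, 0)
        z = -np.logspace(-9, np.log10(0.1), 300)
        exact = lambert_w_m1(z)
        assert np.max(np.abs((_wm1_series(z) - exact) / exact)) < 4e-3


class TestRelativePowerScale:
    def test_endpoints_and_midpoint(self):
        assert relative_power(1.2, 1.2, 25.0) == 0.0
        assert relative_power(25.0, 1.2, 25.0) == 1.0
        assert relative_power(13.1, 1.2, 25.0) == pytest.approx(0.5)

    def test_requires_reserve(self):
        with pytest.raises(ValueError):
            relative_power(5.0, 10.0, 10.0)

    def test_running_economy_is_linear(self, wr_men):
        assert economy_relative_power(wr_men.v_m, wr_men) == pytest.approx(1.0)
        assert economy_relative_power(0.0, wr_men) == 0.0
        assert economy_relative_power(370.548, wr_men) == pytest.approx(0.9)


class TestPowerDuration:
    def test_crossover_anchors(self, wr_men):
        tc = wr_men.t_c
        assert p_max(tc, wr_men) == pytest.approx(1.0, abs=1e-14)
        assert p_max(tc * math.e, wr_men) == pytest.approx(1.0 - wr_men.gamma_l)
        assert p_max(tc / math.e, wr_men) == pytest.approx(1.0 + wr_men.gamma_s)

    def test_absolute_scale(self, wr_men):
        prof = AthleteProfile(**{**wr_men.as_dict(), "P_b": 1.2, "P_m": 25.0})
        assert p_max(prof.t_c, prof, relative=False) == pytest.approx(25.0)
        with pytest.raises(ValueError):
            p_max(5.0, wr_men, relative=False)  # no P_m on the profile

    def test_non_increasing(self, wr_men):
        T = np.geomspace(0.5, 300, 200)
        vals = p_max(T, wr_men)
        assert np.all(np.diff(vals) < 0)

    def test_rejects_nonpositive_duration(self, wr_men):
        with pytest.raises(ModelDomainError):
            p_max(0.0, wr_men)

    def test_inverse_of_duration_at_relative_power(self, wr_men):
        T = np.geomspace(wr_men.t_c / 20, wr_men.t_c * 20, 41)
        back = duration_at_relative_power(p_max(T, wr_men), wr_men)
        np.testing.assert_allclose(back, T, rtol=1e-9)


class TestSupplementalPower:
    def test_short_branch_is_constant(self, wr_men):
        assert supplemental_power_rel(wr_men.t_c, wr_men) == pytest.approx(wr_men.gamma_s)
        assert supplemental_power_rel(wr_men.t_c / 5, wr_men) == pytest.approx(wr_men.gamma_s)

    def test_long_branch_value_and_limit(self, wr_men):
        # (gamma_s - gamma_l)/2 + gamma_l at twice the crossover time
        assert supplemental_power_rel(2 * wr_men.t_c, wr_men) == pytest.approx(0.07675)
        assert supplemental_power_rel(1e9, wr_men) == pytest.approx(wr_men.gamma_l, rel=1e-6)

    def test_factor_peaks_at_crossover(self, wr_men):
        assert supplemental_factor(wr_men.t_c, wr_men) == pytest.approx(1.0 + wr_men.gamma_s)
        T = np.geomspace(0.5, 300, 100)
        f = supplemental_factor(T, wr_men)
        assert np.all(f > 1.0)
        assert np.all(f <= 1.0 + wr_men.gamma_s + 1e-12)

    def test_factor_at_twice_crossover(self, wr_men):
        expect = 1.0 + (1.0 + (0.0999 / 0.0536 - 1.0) / 2.0) / (1.0 / 0.0536 - math.log(2.0))
        assert supplemental_factor(2 * wr_men.t_c, wr_men) == pytest.approx(expect, rel=1e-12)

    def test_factor_domain_error(self, wr_men):
        too_long = wr_men.t_c * math.exp(1.0 / wr_men.gamma_l + 1.0)
        with pytest.raises(ModelDomainError):
            supplemental_factor(too_long, wr_men)


class TestDurations:
    def test_sustainable_duration_anchors(self, wr_men):
        tc = wr_men.t_c
        summary = endurance_summary(wr_men)
        assert duration_at_relative_power(1.0, wr_men) == pytest.approx(tc)
        assert duration_at_relative_power(0.9, wr_men) == pytest.approx(tc * summary.E_l)
        assert duration_at_relative_power(1.1, wr_men) == pytest.approx(tc * summary.E_s)
        with pytest.raises(ModelDomainError):
            duration_at_relative_power(0.0, wr_men)

    def test_duration_at_velocity(self, wr_men):
        tc, vm = wr_men.t_c, wr_men.v_m
        assert duration_at_velocity(vm, wr_men) == pytest.approx(tc)
        assert duration_at_velocity(0.9 * vm, wr_men) == pytest.approx(
            tc * math.exp(0.1 / wr_men.gamma_l)
        )
        # 110% of v_m holds for t_c * E_s = 2.30 min for the men's records
        assert duration_at_velocity(1.1 * vm, wr_men) == pytest.approx(2.30, abs=0.01)

    def test_sub_minute_warns(self, wr_men):
        with pytest.warns(UserWarning, match="oxygen-kinetics"):
            duration_at_velocity(1.5 * wr_men.v_m, wr_men)


class TestRaceTime:
    def test_crossover_distance(self, wr_men):
        assert race_time(wr_men.d_c, wr_men) == pytest.approx(wr_men.t_c, rel=1e-12)
        assert mean_race_velocity(wr_men.d_c, wr_men) == pytest.approx(wr_men.v_m, rel=1e-12)

    @pytest.mark.parametrize(
        "d,clock",
        [(1000.0, "02:11.94"), (42195.0, "2:01:52.99")],
    )
    def test_world_record_times(self, wr_men, d, clock):
        from runpower import parse_time

        expect = parse_time(clock)
        assert race_time(d, wr_men) == pytest.approx(expect, rel=1e-3)

    def test_strictly_increasing(self, wr_men):
        d = np.geomspace(800, 60000, 100)
        T = race_time(d, wr_men)
        assert np.all(np.diff(T) > 0)
        v = mean_race_velocity(d, wr_men)
        assert np.all(np.diff(v) < 0)

    def test_round_trip_with_duration_at_velocity(self, wr_men):
        for d in (900.0, wr_men.d_c, 5000.0, 42195.0):
            T = race_time(d, wr_men)
            assert duration_at_velocity(d / T, wr_men) == pytest.approx(T, rel=1e-9)

    def test_velocity_identity(self, wr_men):
        d = 42195.0
        assert mean_race_velocity(d, wr_men) == pytest.approx(d / race_time(d, wr_men))
        assert mean_race_velocity(d, wr_men) == pytest.approx(346.2, abs=0.5)

    def test_rescaled_identity(self, wr_men):
        rc = rescaled_coordinates(10000.0, wr_men)
        assert rc.tau == pytest.approx(rc.delta - rc.upsilon, abs=1e-14)

    def test_domain_errors(self, wr_men):
        with pytest.raises(ModelDomainError):
            race_time(-5.0, wr_men)
        with pytest.raises(ModelDomainError):
            race_time(1e12, wr_men)  # Lambert argument below -1/e


class TestAsymptoticExpansion:
    def test_accuracy_over_record_distances(self, wr_men):
        for d in (800, 1000, 1500, 1609.34, 3000, 5000, 10000, 21097.5, 42195.0):
            exact = race_time(float(d), wr_men)
            approx = wr_men.t_c * math.exp(approx_race_time(float(d), wr_men).tau)
            assert abs(approx - exact) / exact < 4e-3

    def test_crossover_distance_maps_to_origin(self, wr_men):
        rc = approx_race_time(wr_men.d_c, wr_men)
        assert rc.delta == 0.0
        assert abs(rc.tau) < 1e-4  # series truncation only

    def test_warns_outside_small_argument_regime(self):
        prof = AthleteProfile(t_c=6.0, v_m=400.0, gamma_s=0.1, gamma_l=0.3)
        with pytest.warns(UserWarning, match="series"):
            approx_race_time(prof.d_c * 1.7, prof)


class TestEnduranceAndConsistency:
    def test_printed_record_indices(self, wr_men):
        s = endurance_summary(wr_men)
        assert round(s.E_l, 2) == 6.46
        assert round(s.E_s, 2) == 0.37
        assert s.d_c == pytest.approx(6.26 * 411.72)

    def test_unit_exponent(self):
        prof = AthleteProfile(t_c=6.0, v_m=400.0, gamma_s=0.1, gamma_l=0.1)
        assert endurance_summary(prof).E_l == pytest.approx(math.e)

    def test_threshold_intensity(self, wr_women, vdot40):
        assert threshold_intensity(vdot40) == pytest.approx(91.94, abs=0.005)
        assert threshold_intensity(wr_women) == pytest.approx(90.41, abs=0.005)
        prof = AthleteProfile(t_c=60.0, v_m=300.0, gamma_s=0.1, gamma_l=0.05)
        assert threshold_intensity(prof) == pytest.approx(100.0)

    @pytest.mark.parametrize("T", [0.5, 3.0, 6.26, 30.0, 120.0, 300.0])
    def test_self_consistency_residual(self, wr_men, T):
        assert abs(verify_self_consistency(wr_men, T)) < 1e-8


class TestProfileValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"t_c": 0.0},
            {"v_m": -1.0},
            {"gamma_s": 0.0},
            {"gamma_l": 1.5},
            {"gamma_l": 1e-4},  # below the degeneracy floor
            {"P_b": 10.0, "P_m": 5.0},
        ],
    )
    def test_invalid_profiles_rejected(self, kw):
        base = dict(t_c=6.0, v_m=400.0, gamma_s=0.1, gamma_l=0.05)
        with pytest.raises(ValueError):
            AthleteProfile(**{**base, **kw})
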