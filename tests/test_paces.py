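"""Characteristic velocities and pace tables at prescribed intensity."""

import math
from dataclasses import replace

import pytest

from runpower import (
    MARATHON,
    ModelDomainError,
    PaceQuery,
    ProfileVariant,
    STANDARD_PACE_QUERIES,
    ENDURANCE_VARIANTS,
    pace_table,
    threshold_intensity,
    velocity_at_intensity_distance,
    velocity_at_intensity_duration,
)


class TestVelocityAtDuration:
    def test_crossover_anchor(self, vdot40):
        assert velocity_at_intensity_duration(1.0, vdot40.t_c, vdot40) == pytest.approx(
            vdot40.v_m
        )

    def test_linear_in_intensity(self, vdot40):
        v1 = velocity_at_intensity_duration(1.0, 45.0, vdot40)
        v09 = velocity_at_intensity_duration(0.9, 45.0, vdot40)
        assert v09 == pytest.approx(0.9 * v1, rel=1e-12)

    def test_threshold_pace_matches_reference(self, vdot40):
        # 60-min race pace of the VDOT-40 runner: 05:03.67 per km
        v = velocity_at_intensity_duration(1.0, 60.0, vdot40)
        assert 60000.0 / v == pytest.approx(303.67, abs=0.2)

    def test_domain_error_for_extreme_duration(self, vdot40):
        too_long = vdot40.t_c * math.exp(1.0 / vdot40.gamma_l + 0.1)
        with pytest.raises(ModelDomainError):
            velocity_at_intensity_duration(1.0, too_long, vdot40)


class TestVelocityAtDistance:
    def test_marathon_pace_matches_reference(self, vdot40):
        v = velocity_at_intensity_distance(1.0, MARATHON, vdot40)
        assert 60000.0 / v == pytest.approx(328.16, abs=0.2)

    def test_marathon_pace_low_endurance_variant(self, vdot40):
        prof = replace(vdot40, gamma_l=0.08)
        v = velocity_at_intensity_distance(1.0, MARATHON, prof)
        assert 60000.0 / v == pytest.approx(369.16, abs=0.2)

    def test_reduces_to_race_velocity_at_crossover(self, vdot40):
        v = velocity_at_intensity_distance(1.0, vdot40.d_c, vdot40)
        assert v == pytest.approx(vdot40.v_m, rel=1e-12)

    @pytest.mark.parametrize("p_hat", [0.8, 0.95, 1.0])
    @pytest.mark.parametrize("d", [5000.0, 42195.0])
    def test_duration_distance_consistency(self, vdot40, p_hat, d):
        # cover d at the returned v -> takes T = d/v; the duration form at
        # the same intensity must give the same velocity back
        v = velocity_at_intensity_distance(p_hat, d, vdot40)
        T = d / v
        assert velocity_at_intensity_duration(p_hat, T, vdot40) == pytest.approx(
            v, rel=1e-9
        )

    def test_monotone_in_distance_and_intensity(self, vdot40):
        paces = [
            60000.0 / velocity_at_intensity_distance(1.0, d, vdot40)
            for d in (5000.0, 10000.0, 21097.5, 42195.0)
        ]
        assert paces == sorted(paces)
        slower = 60000.0 / velocity_at_intensity_distance(0.9, 10000.0, vdot40)
        faster = 60000.0 / velocity_at_intensity_distance(1.0, 10000.0, vdot40)
        assert slower > faster


class TestSensitivityDirections:
    def test_gamma_l_only_touches_long_efforts(self, vdot40):
        worse = replace(vdot40, gamma_l=0.08)
        for T in (30.0, 60.0, 180.0):  # beyond t_c
            assert velocity_at_intensity_duration(1.0, T, worse) < (
                velocity_at_intensity_duration(1.0, T, vdot40)
            )
        for T in (3.0, 8.0):  # below t_c
            assert velocity_at_intensity_duration(1.0, T, worse) == pytest.approx(
                velocity_at_intensity_duration(1.0, T, vdot40)
            )

    def test_gamma_s_only_touches_short_efforts(self, vdot40):
        better = replace(vdot40, gamma_s=0.15)
        for T in (3.0, 8.0):
            assert velocity_at_intensity_duration(1.0, T, better) > (
                velocity_at_intensity_duration(1.0, T, vdot40)
            )
        for T in (30.0, 60.0):
            assert velocity_at_intensity_duration(1.0, T, better) == pytest.approx(
                velocity_at_intensity_duration(1.0, T, vdot40)
            )


class TestPaceTable:
    def test_empty_queries_give_empty_grid(self, vdot40):
        table = pace_table(vdot40, [])
        assert table.rows == ()

    def test_crossover_row_invariant_under_endurance_variants(self, vdot40):
        table = pace_table(vdot40, STANDARD_PACE_QUERIES, ENDURANCE_VARIANTS)
        i_row = table.rows[2]  # the at-crossover query
        for entry in i_row[1:]:
            assert entry.pace_s_per_km == pytest.approx(i_row[0].pace_s_per_km)

    def test_crossover_row_shifts_under_tc_variants(self, vdot40):
        table = pace_table(
            vdot40, STANDARD_PACE_QUERIES, [ProfileVariant("0.8 t_c", tc_factor=0.8)]
        )
        i_row = table.rows[2]
        assert i_row[1].pace_s_per_km > i_row[0].pace_s_per_km

    def test_invalid_cells_are_marked_not_raised(self, vdot40):
        q = PaceQuery(duration=1e10, label="absurd")
        table = pace_table(vdot40, [q])
        assert not table.rows[0][0].valid
        assert math.isnan(table.rows[0][0].pace_s_per_km)

    def test_per_mile_conversion(self, vdot40):
        table = pace_table(vdot40, [PaceQuery(duration=60.0, label="T")])
        entry = table.rows[0][0]
        assert entry.pace_s_per_mile == pytest.approx(entry.pace_s_per_km * 1.60934)

    def test_render_contains_queries_and_variants(self, vdot40):
        table = pace_table(vdot40, STANDARD_PACE_QUERIES, ENDURANCE_VARIANTS)
        text = table.render()
        assert "marathon (M-pace)" in text
        assert "gamma_l=0.04" in text


class TestPaceQueryValidation:
    def test_exactly_one_target(self):
        with pytest.raises(ValueError):
            PaceQuery(duration=5.0, distance=1000.0)
        with pytest.raises(ValueError):
            PaceQuery()

    def test_intensity_bounds(self):
        with pytest.raises(ValueError):
            PaceQuery(intensity=1.3, duration=5.0)
        with pytest.warns(UserWarning, match="supra-maximal"):
            PaceQuery(intensity=1.1, duration=5.0)


class TestThresholdIntensity:
    def test_reference_values(self, vdot40, wr_women):
        assert threshold_intensity(vdot40) == pytest.approx(91.94, abs=0.005)
        assert threshold_intensity(wr_women) == pytest.approx(90.41, abs=0.005)
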