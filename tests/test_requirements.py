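"""Factorial requirement arithmetic: egg components, scheduling, maintenance, growth."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eggsim import (
    EggComponents,
    GrowthParams,
    MaintenanceParams,
    NutrientConstants,
    egg_amino_acids,
    egg_energy,
    egg_ideal_protein,
    egg_nitrogen_mg,
    growth_requirement,
    hen_requirement_series,
    maintenance,
    schedule_yolk_demand,
    total_requirement,
)
from eggsim.ovulation import OvipositionRecord


def _rec(day, yolk=18.0, albumen=36.0, shell=6.0, quality="normal", hen_id=0):
    return OvipositionRecord(
        hen_id=hen_id, day=day, time_of_lay_h=9.0, clutch_index=1,
        position_in_clutch=1, quality=quality, yolk_g=yolk, albumen_g=albumen,
        shell_g=shell,
    )


class TestEggEnergy:
    def test_zero_components(self):
        assert egg_energy(EggComponents(0, 0, 0)) == 0.0

    def test_per_gram_coefficients(self):
        assert egg_energy(EggComponents(1, 0, 0)) == pytest.approx(2.5)
        assert egg_energy(EggComponents(0, 1, 0)) == pytest.approx(2.6)
        assert egg_energy(EggComponents(0, 0, 1)) == pytest.approx(1.2)

    def test_linear_combination(self):
        assert egg_energy(EggComponents(18, 36, 6)) == pytest.approx(145.8)


class TestEggIdealProtein:
    def test_per_gram_coefficients_at_unit_efficiency(self):
        assert egg_ideal_protein(EggComponents(1, 0, 0), efficiency=1.0) == pytest.approx(0.21)
        assert egg_ideal_protein(EggComponents(0, 1, 0), efficiency=1.0) == pytest.approx(0.13)
        assert egg_ideal_protein(EggComponents(0, 0, 1), efficiency=1.0) == pytest.approx(0.004)

    def test_default_efficiency_is_080(self):
        assert egg_ideal_protein(EggComponents(1, 0, 0)) == pytest.approx(0.21 / 0.80)

    def test_composite_egg(self):
        # (0.21*18 + 0.13*36 + 0.004*6) / 0.8
        assert egg_ideal_protein(EggComponents(18, 36, 6)) == pytest.approx(10.605)

    def test_efficiency_scaling(self):
        """Halving efficiency doubles protein and amino acids; energy unchanged."""
        c = EggComponents(16, 34, 5)
        assert egg_ideal_protein(c, efficiency=0.4) == pytest.approx(
            2 * egg_ideal_protein(c, efficiency=0.8)
        )
        aa_lo = egg_amino_acids(c, efficiency=0.4)
        aa_hi = egg_amino_acids(c, efficiency=0.8)
        for k in aa_lo:
            assert aa_lo[k] == pytest.approx(2 * aa_hi[k])
        assert egg_energy(c) == egg_energy(c)


class TestEggAminoAcids:
    def test_yolk_nitrogen(self):
        assert egg_nitrogen_mg(EggComponents(1, 0, 0)) == pytest.approx(27.0)

    def test_albumen_nitrogen(self):
        assert egg_nitrogen_mg(EggComponents(0, 1, 0)) == pytest.approx(17.0)

    def test_unit_profile(self):
        k = NutrientConstants(aa_profile_mg_per_mg_n={"x": 1.0})
        aa = egg_amino_acids(EggComponents(1, 1, 0), k, efficiency=1.0)
        assert aa["x"] == pytest.approx(0.044)  # (27 + 17) mg as g

    def test_every_amino_acid_below_ideal_protein(self):
        c = EggComponents(18, 36, 6)
        ip = egg_ideal_protein(c)
        for amount in egg_amino_acids(c).values():
            assert amount < ip


class TestYolkSchedule:
    def test_single_egg_spread_at_2_g_per_day(self):
        out = schedule_yolk_demand([_rec(day=20, yolk=18.0)], 30)
        window = out[10:19]
        np.testing.assert_allclose(window, 2.0)
        assert out.sum() == pytest.approx(18.0)

    def test_no_records_zero_demand(self):
        assert schedule_yolk_demand([], 10).sum() == 0.0

    def test_daily_laying_steady_state_overlap(self):
        recs = [_rec(day=d, yolk=18.0) for d in range(10, 40)]
        out = schedule_yolk_demand(recs, 40)
        np.testing.assert_allclose(out[15:30], 18.0)  # 9 overlapping follicles x 2 g

    def test_remainder_on_first_day_conserves_mass(self):
        out = schedule_yolk_demand([_rec(day=20, yolk=17.5)], 30)
        assert out.sum() == pytest.approx(17.5)
        assert out[10] == pytest.approx(1.5)  # first follicular day carries the remainder

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        yolks=st.lists(st.floats(8.0, 22.0), min_size=1, max_size=15),
    )
    def test_conservation_for_interior_eggs(self, yolks):
        recs = [_rec(day=20 + 2 * i, yolk=y) for i, y in enumerate(yolks)]
        horizon = 20 + 2 * len(yolks) + 5
        out = schedule_yolk_demand(recs, horizon)
        assert out.sum() == pytest.approx(sum(yolks))


class TestMaintenance:
    def test_zero_body_protein(self):
        req = maintenance(0.0)
        assert req.energy_kj_per_d == 0.0 and req.ideal_protein_g_per_d == 0.0

    def test_linear_in_body_protein(self):
        p = MaintenanceParams(bp_exponent=1.0)
        assert maintenance(500.0, p).energy_kj_per_d == pytest.approx(
            2 * maintenance(250.0, p).energy_kj_per_d
        )

    def test_breeder_exceeds_layer(self):
        assert maintenance(494.0).energy_kj_per_d > maintenance(254.0).energy_kj_per_d
        assert maintenance(494.0).ideal_protein_g_per_d > maintenance(254.0).ideal_protein_g_per_d


class TestGrowth:
    def test_zero_after_first_egg(self):
        req = growth_requirement(150.0, 150.0, 30.0)
        assert req.energy_kj_per_d == 0.0 and req.ideal_protein_g_per_d == 0.0

    def test_linear_schedule(self):
        p = GrowthParams(efficiency=1.0)
        req = growth_requirement(130.0, 140.0, 20.0, p)
        assert req.ideal_protein_g_per_d == pytest.approx(2.0)

    def test_zero_remaining_gain(self):
        assert growth_requirement(130.0, 140.0, 0.0).ideal_protein_g_per_d == 0.0


class TestTotalRequirement:
    def test_non_laying_hen_is_maintenance_only(self):
        total = total_requirement(0.0, 0.0, 0.0, 254.0)
        maint = maintenance(254.0)
        assert total.energy_kj_per_d == pytest.approx(maint.energy_kj_per_d)
        assert total.ideal_protein_g_per_d == pytest.approx(maint.ideal_protein_g_per_d)

    def test_sum_of_parts_is_total(self):
        growth = growth_requirement(130.0, 140.0, 20.0)
        total = total_requirement(2.0, 36.0, 6.0, 254.0, growth=growth)
        c = EggComponents(2.0, 36.0, 6.0)
        expect_e = egg_energy(c) + maintenance(254.0).energy_kj_per_d + growth.energy_kj_per_d
        assert total.energy_kj_per_d == pytest.approx(expect_e)

    def test_monotone_in_components_and_body_protein(self):
        base = total_requirement(2.0, 30.0, 5.0, 254.0)
        for kwargs in [
            dict(yolk_deposited_g=3.0, albumen_g=30.0, shell_g=5.0, body_protein_g=254.0),
            dict(yolk_deposited_g=2.0, albumen_g=35.0, shell_g=5.0, body_protein_g=254.0),
            dict(yolk_deposited_g=2.0, albumen_g=30.0, shell_g=6.0, body_protein_g=254.0),
            dict(yolk_deposited_g=2.0, albumen_g=30.0, shell_g=5.0, body_protein_g=300.0),
        ]:
            bigger = total_requirement(**kwargs)
            assert bigger.energy_kj_per_d >= base.energy_kj_per_d
            assert bigger.ideal_protein_g_per_d >= base.ideal_protein_g_per_d


class TestHenRequirementSeries:
    def test_internal_egg_has_yolk_but_no_albumen_shell_demand(self):
        recs = [_rec(day=20, quality="internal")]
        s = hen_requirement_series(recs, afe_d=120, body_protein_afe_g=254.0,
                                   horizon_d=30, start_age_d=120)
        yolk_only = s.egg_energy_kj.sum()
        assert yolk_only == pytest.approx(2.5 * 18.0)  # no 2.6*albumen or 1.2*shell

    def test_yolk_conservation_over_horizon(self):
        recs = [_rec(day=d) for d in range(15, 40, 2)]
        s = hen_requirement_series(recs, afe_d=120, body_protein_afe_g=254.0,
                                   horizon_d=50, start_age_d=120)
        # energy over the horizon equals the per-egg totals (all follicles interior)
        assert s.egg_energy_kj.sum() == pytest.approx(len(recs) * egg_energy(EggComponents(18, 36, 6)))

    def test_maintenance_constant_after_first_egg(self):
        s = hen_requirement_series([], afe_d=140, body_protein_afe_g=254.0,
                                   horizon_d=60, start_age_d=120,
                                   body_protein_start_g=210.0)
        after = s.priority_energy_kj[25:]
        np.testing.assert_allclose(after, after[0])
        # growth makes pre-lay priority protein exceed the laying-period value
        assert np.all(s.priority_ideal_protein_g[:19] > s.priority_ideal_protein_g[-1])

    def test_growth_zero_on_and_after_afe_day(self):
        s = hen_requirement_series([], afe_d=130, body_protein_afe_g=254.0,
                                   horizon_d=40, start_age_d=120,
                                   body_protein_start_g=230.0)
        maint_only = MaintenanceParams().energy_kj_per_kg_bp * 254.0 / 1000.0
        np.testing.assert_allclose(s.priority_energy_kj[10:], maint_only)
        assert np.all(s.priority_energy_kj[:10] > maint_only)
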