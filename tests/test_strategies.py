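"""Strategy inclusion/exclusion rules, titration and the stress cascade."""

import numpy as np
import pandas as pd
import pytest

import chdprevent as cp
from chdprevent.strategies import (assign_atp3, assign_accaha, assign_jupiter,
                                   assign_shape, assign_texas, assign_treat_all,
                                   assign_status_quo, shape_stress_cascade)
from conftest import make_profile


class TestAtp3:
    def test_goal_met_no_statin_but_aspirin(self, params):
        p = make_profile(frs10=0.12, ldl=120.0)   # goal <130 already met
        plan = assign_atp3(p, params)
        assert plan.statin1 == "none"
        assert plan.aspirin

    def test_titration_chooses_minimum_sufficient_dose(self, params):
        # FRS 25%, LDL 180: moderate leaves 118.8 > 100, high reaches 81
        p = make_profile(frs10=0.25, ldl=180.0)
        assert assign_atp3(p, params).statin1 == "high"
        # FRS 25%, LDL 140: moderate reaches 92.4 < 100
        p = make_profile(frs10=0.25, ldl=140.0)
        assert assign_atp3(p, params).statin1 == "moderate"

    def test_women_never_get_aspirin(self, params):
        p = make_profile(sex="female", age_entry=60, frs10=0.15, ldl=150.0)
        assert not assign_atp3(p, params).aspirin

    @pytest.mark.parametrize("frs,goal", [(0.04, 160.0), (0.12, 130.0), (0.25, 100.0)])
    def test_goals_by_frs_band(self, params, frs, goal):
        p = make_profile(frs10=frs, ldl=50.1 + 200)
        assert assign_atp3(p, params).ldl_goal == goal


class TestAccAha:
    def test_high_dose_above_pce_threshold(self, params, tables):
        # female map is identity, so FRS 8% -> PCE 8% >= 7.5%
        p = make_profile(sex="female", age_entry=60, frs10=0.08, ldl=150.0)
        assert assign_accaha(p, params, tables).statin1 == "high"

    def test_low_ldl_excluded_despite_high_risk(self, params, tables):
        p = make_profile(sex="female", age_entry=60, frs10=0.30, ldl=60.0)
        assert assign_accaha(p, params, tables).statin1 == "none"

    def test_high_ldl_treated_regardless_of_pce(self, params, tables):
        p = make_profile(frs10=0.02, ldl=200.0)
        assert assign_accaha(p, params, tables).statin1 == "high"

    def test_moderate_dose_variant_for_intermediate_pce(self, params, tables):
        p = make_profile(sex="female", age_entry=60, frs10=0.06, ldl=150.0)
        assert assign_accaha(p, params, tables).statin1 == "none"
        assert assign_accaha(p, params, tables,
                             moderate_5to7=True).statin1 == "moderate"


class TestJupiter:
    def test_inclusion(self, params):
        p = make_profile(age_entry=55, ldl=110.0, crp=3.1)
        plan = assign_jupiter(p, params)
        assert plan.statin1 == "rosuvastatin"
        assert plan.crp_tested and plan.switch_year == 0

    def test_young_man_tested_on_reaching_window(self, params):
        p = make_profile(age_entry=47, ldl=110.0, crp=3.1, frs10=0.08)
        plan = assign_jupiter(p, params)
        assert plan.switch_year == 3           # tested at 50
        assert plan.statin0 == assign_atp3(p, params).statin1  # interim rule
        assert plan.statin1 == "rosuvastatin"

    def test_high_ldl_falls_through_to_goal_rule(self, params):
        p = make_profile(sex="female", age_entry=62, ldl=150.0, crp=5.0,
                         frs10=0.04)
        plan = assign_jupiter(p, params)
        assert plan.statin1 == assign_atp3(p, params).statin1
        assert plan.statin1 != "rosuvastatin"


class TestShape:
    def test_cac_zero_gets_lenient_goal(self, params, tables):
        p = make_profile(age_entry=55, n_shape_risk_factors=1, cac_category="0")
        plan = assign_shape(p, params, tables)
        assert plan.cac_tested and plan.ldl_goal == 160.0

    def test_high_cac_triggers_stress_cascade(self, params, tables):
        p = make_profile(age_entry=55, n_shape_risk_factors=1,
                         cac_category="401-1000")
        plan = assign_shape(p, params, tables)
        assert plan.ldl_goal == 70.0
        assert plan.stress_test

    def test_below_window_deferred_with_interim_goal_rule(self, params, tables):
        p = make_profile(sex="female", age_entry=58, frs10=0.04, ldl=150.0,
                         n_shape_risk_factors=1)
        plan = assign_shape(p, params, tables)
        assert plan.test_year == 2             # scanned once she turns 60
        assert plan.statin0 == assign_atp3(p, params).statin1

    def test_no_risk_factors_exit_to_goal_rule(self, params, tables):
        p = make_profile(age_entry=55, frs10=0.04, n_shape_risk_factors=0,
                         cac_category=">1000")
        plan = assign_shape(p, params, tables)
        assert not plan.cac_tested
        assert plan.ldl_goal == 160.0


class TestTexas:
    def test_intermediate_risk_scanned(self, params, tables):
        p = make_profile(age_entry=60, frs10=0.15, cac_category="101-400")
        plan = assign_texas(p, params, tables)
        assert plan.cac_tested and plan.ldl_goal == 100.0

    def test_low_risk_not_scanned(self, params, tables):
        p = make_profile(age_entry=60, frs10=0.08)
        plan = assign_texas(p, params, tables)
        assert not plan.cac_tested

    def test_identical_to_goal_rule_on_low_risk_roster(self, params, tables,
                                                       roster_male):
        low = roster_male[roster_male.frs10 < 0.10].reset_index(drop=True)
        tex = assign_texas(low, params, tables)
        atp = assign_atp3(low, params)
        assert (tex.statin1 == atp.statin1).all()
        assert not tex.cac_tested.any()


class TestTreatAll:
    def test_everyone_on_statin_women_no_aspirin(self, params):
        p = make_profile(sex="female", age_entry=60, frs10=0.01)
        plan = assign_treat_all(p, intensity="high")
        assert plan.statin1 == "high" and not plan.aspirin

    def test_low_risk_man_gets_both(self, params):
        p = make_profile(frs10=0.02)
        plan = assign_treat_all(p, intensity="high")
        assert plan.statin1 == "high" and plan.aspirin

    def test_moderate_intensity(self, params):
        assert assign_treat_all(make_profile(),
                                intensity="moderate").statin1 == "moderate"


class TestStatusQuo:
    def test_band_rates_recovered(self, params, tables):
        n = 20_000
        roster = cp.sample_cohort(n, "male", tables, seed=21)
        plan = assign_status_quo(roster, params, tables, seed=21)
        band = roster.age_entry.between(55, 64)
        frac = (plan.statin1[band.to_numpy()] == "moderate").mean()
        se = np.sqrt(0.301 * 0.699 / band.sum())
        assert abs(frac - 0.301) < 3 * se

    def test_women_aspirin_rate_zeroed_by_sex_rule(self, params, tables):
        roster = cp.sample_cohort(5000, "female", tables, seed=22)
        plan = assign_status_quo(roster, params, tables, seed=22)
        assert not plan.aspirin.any()          # aspirin modelled for men only

    def test_zero_rate_band_never_treated(self, params, tables):
        t = cp.DistributionTables(
            **{f: getattr(tables, f).copy() for f in tables._FILES})
        t.status_quo_use["statin_rate"] = 0.0
        t.validate()
        roster = cp.sample_cohort(2000, "male", tables, seed=23)
        plan = assign_status_quo(roster, params, t, seed=23)
        assert (plan.statin1 == "none").all()


class TestStressCascade:
    def test_disabled_cascade_only_tests(self, params):
        p = params.copy()
        p.set("stress_cascade.p_moderate_severe_ischemia", 0.0)
        out = shape_stress_cascade(np.ones(1000, bool), p, seed=1)
        assert out["stress_test"].all()
        assert not out["ischemia"].any()
        assert not out["revascularized"].any()

    def test_cascade_fractions_binomial(self, params):
        n = 100_000
        out = shape_stress_cascade(np.ones(n, bool), params, seed=2)
        frac_isch = out["ischemia"].mean()
        se = np.sqrt(0.31 * 0.69 / n)
        assert abs(frac_isch - 0.31) < 3 * se
        n_isch = out["ischemia"].sum()
        frac_pci = out["pci"].sum() / n_isch
        frac_cabg = out["cabg"].sum() / n_isch
        assert abs(frac_pci - 0.33) < 3 * np.sqrt(0.33 * 0.67 / n_isch)
        assert abs(frac_cabg - 0.19) < 3 * np.sqrt(0.19 * 0.81 / n_isch)
        assert not (out["pci"] & out["cabg"]).any()


class TestAssignmentInvariants:
    def test_deterministic_given_seed(self, params, tables, roster_male):
        for name in cp.STRATEGIES:
            a = cp.assign(name, roster_male, params, tables, seed=5)
            b = cp.assign(name, roster_male, params, tables, seed=5)
            pd.testing.assert_frame_equal(a, b)

    def test_every_person_gets_exactly_one_plan(self, params, tables, roster_male):
        for name in cp.STRATEGIES:
            plan = cp.assign(name, roster_male, params, tables, seed=5)
            assert len(plan) == len(roster_male)
            assert plan.statin1.isin(["none", "moderate", "high",
                                      "rosuvastatin"]).all()

    def test_accaha_treats_at_least_as_many_as_atp3(self, params, tables,
                                                    roster_male, roster_female):
        for roster in (roster_male, roster_female):
            acc = (assign_accaha(roster, params, tables).statin1 != "none").mean()
            atp = (assign_atp3(roster, params).statin1 != "none").mean()
            assert acc >= atp

    def test_texas_scans_fewer_than_shape(self, params, tables, roster_male):
        shape = assign_shape(roster_male, params, tables, seed=5)
        texas = assign_texas(roster_male, params, tables, seed=5)
        # roster contains low-FRS persons with risk factors, whom only the
        # population-screening strategy scans
        assert texas.cac_tested.sum() < shape.cac_tested.sum()

    def test_aspirin_only_for_men(self, params, tables, roster_female):
        for name in cp.STRATEGIES:
            plan = cp.assign(name, roster_female, params, tables, seed=5)
            assert not plan.aspirin.any()
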