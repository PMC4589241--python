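"""Simulation engine: state transitions, accrual, adverse events, scaling."""

import numpy as np
import pandas as pd
import pytest

import chdprevent as cp
from chdprevent.microsim import (apply_medication_adverse_events,
                                 apply_radiation_risk, scale_to_population)

SEED = 1


def _clone_tables(tables):
    return cp.DistributionTables(
        **{f: getattr(tables, f).copy() for f in tables._FILES})


class TestStepAccrual:
    def test_zero_horizon_zero_tallies(self, roster_male, params, tables):
        res = cp.run_cohort(roster_male, "atp3", params, tables, horizon=0,
                            seed=SEED)
        assert res.qaly_discounted == 0 and res.cost_discounted == 0
        assert all(v == 0 for k, v in res.counts.items()
                   if k not in ("on_statin", "on_aspirin"))

    def test_no_hazards_yields_discounted_annuity(self, params, tables):
        # zero background mortality and zero CHD risk: everyone survives 30
        # years in full health and QALYs equal the 3%-discount annuity
        t = _clone_tables(tables)
        t.mortality["annual_prob"] = 0.0
        t.validate()
        n = 200
        roster = cp.sample_cohort(n, "male", t, seed=3)
        roster["frs10"] = 0.0
        roster["ldl"] = 50.0          # below every goal: nobody treated
        plan = cp.assign_atp3(roster, params)
        assert (plan.statin1 == "none").all()
        plan["aspirin"] = False
        res = cp.run_cohort(roster, plan, params, t, seed=SEED)
        annuity = sum(1.03 ** (-k) for k in range(30))
        assert res.qaly_discounted / n == pytest.approx(annuity, rel=1e-12)
        assert res.life_years == 30 * n
        assert res.cost_discounted == 0.0

    def test_mi_year_cost_includes_upfront(self, params, tables):
        t = _clone_tables(tables)
        t.mortality["annual_prob"] = 0.0
        t.validate()
        n = 2000
        roster = cp.sample_cohort(n, "male", t, seed=4)
        roster["frs10"] = 0.9         # high annual hazard, many events
        roster["ldl"] = 50.0
        plan = cp.assign_atp3(roster, params)
        plan["aspirin"] = False
        p0 = params.copy()
        p0.set("mi.cost_upfront", 0.0)
        with_up = cp.run_cohort(roster, plan, params, t, seed=SEED)
        without = cp.run_cohort(roster, plan, p0, t, seed=SEED)
        upfront = params.get("mi.cost_upfront")
        nonfatal = with_up.counts["nonfatal_mi"]
        assert nonfatal > 0
        delta = with_up.cost_discounted - without.cost_discounted
        # each surviving MI contributes one upfront payment, discounted
        assert upfront * nonfatal * 1.03 ** (-29) <= delta <= upfront * nonfatal

    def test_dead_accrue_nothing(self, params, tables):
        t = _clone_tables(tables)
        t.mortality["annual_prob"] = 1.0   # everyone dies in cycle one
        t.validate()
        roster = cp.sample_cohort(100, "male", t, seed=5)
        res = cp.run_cohort(roster, "treat_all_high", params, t, seed=SEED)
        assert res.life_years == 0
        assert res.qaly_discounted == 0
        assert res.counts["deaths_other"] == 100


class TestMedicationAdverseEvents:
    def test_no_statin_no_events(self, params):
        rng = np.random.default_rng(0)
        years = apply_medication_adverse_events(
            np.array(["none"] * 1000, object), np.array(["none"] * 1000, object),
            np.zeros(1000, int), params, rng)
        assert all((y == -1).all() for y in years.values())

    def test_high_dose_hepatitis_rate(self, params):
        n = 100_000
        rng = np.random.default_rng(1)
        years = apply_medication_adverse_events(
            np.array(["high"] * n, object), np.array(["high"] * n, object),
            np.zeros(n, int), params, rng)
        count = (years["hepatitis"] >= 0).sum()
        se = np.sqrt(n * 0.0135 * (1 - 0.0135))
        assert abs(count - n * 0.0135) < 3 * se

    def test_moderate_incidences_are_half_of_high(self, params):
        # "roughly half": exact for the meta-analysed events, and the
        # published diabetes incidences are 0.001 vs 0.003
        for ae in ("hepatitis", "liver_failure", "myopathy", "rhabdomyolysis"):
            hi = params.get(f"statin.high.adverse_events.{ae}.incidence")
            mod = params.get(f"statin.moderate.adverse_events.{ae}.incidence")
            assert mod == pytest.approx(0.5 * hi, rel=0.05), ae
        ratio = (params.get("statin.moderate.adverse_events.diabetes.incidence")
                 / params.get("statin.high.adverse_events.diabetes.incidence"))
        assert 0.3 <= ratio <= 0.55

    def test_escalation_adds_only_incremental_risk(self, params):
        n = 200_000
        rng = np.random.default_rng(2)
        years = apply_medication_adverse_events(
            np.array(["moderate"] * n, object), np.array(["high"] * n, object),
            np.full(n, 5), params, rng)
        hep = years["hepatitis"]
        at_entry = (hep == 0).sum()
        at_switch = (hep == 5).sum()
        total = at_entry + at_switch
        assert abs(at_entry - n * 0.00675) < 3 * np.sqrt(n * 0.00675)
        assert abs(total - n * 0.0135) < 3 * np.sqrt(n * 0.0135)


class TestRadiationRisk:
    def test_zero_scans_no_cancers(self, params, tables):
        rng = np.random.default_rng(0)
        onsets = apply_radiation_risk(np.full(1000, 55.0), "female",
                                      0, 2.3, params, tables, rng)
        assert all((y == -1).all() for y in onsets.values())

    def test_lung_risk_55yo_women(self, params, tables):
        n = 1_000_000
        rng = np.random.default_rng(1)
        onsets = apply_radiation_risk(np.full(n, 55.0), "female", 1, 2.3,
                                      params, tables, rng)
        count = (onsets["lung"] >= 0).sum()
        expected = n * 15.04e-5
        assert abs(count - expected) < 3 * np.sqrt(expected)
        # solid tumours lag 10 years, leukemia 2
        assert (onsets["lung"][onsets["lung"] >= 0] == 10).all()
        assert (onsets["leukemia"][onsets["leukemia"] >= 0] == 2).all()

    def test_linear_no_threshold_dose_scaling(self, params, tables):
        n = 1_000_000
        rng = np.random.default_rng(2)
        double = apply_radiation_risk(np.full(n, 55.0), "female", 1, 4.6,
                                      params, tables, rng)
        count = (double["lung"] >= 0).sum()
        expected = n * 2 * 15.04e-5
        assert abs(count - expected) < 3 * np.sqrt(expected)

    def test_negative_dose_rejected(self, params, tables):
        with pytest.raises(ValueError):
            apply_radiation_risk(np.full(3, 55.0), "female", 1, -1.0, params,
                                 tables, np.random.default_rng(0))


class TestRunCohort:
    def test_seed_reproducibility(self, roster_male, params, tables):
        a = cp.run_cohort(roster_male, "shape", params, tables, seed=9)
        b = cp.run_cohort(roster_male, "shape", params, tables, seed=9)
        assert a.counts == b.counts
        assert a.cost_discounted == b.cost_discounted
        assert a.qaly_discounted == b.qaly_discounted

    def test_qaly_orderings(self, basecase):
        for res in basecase.values():
            for r in res.values():
                assert r.qaly_discounted <= r.qaly_undiscounted + 1e-9
                assert r.qaly_undiscounted <= r.life_years + 1e-9
                assert r.deaths_total <= r.n_simulated

    def test_treat_all_fewer_events_more_adverse_events(self, basecase):
        for sex in basecase:
            sq, th = basecase[sex]["status_quo"], basecase[sex]["treat_all_high"]
            assert th.counts["chd_events"] < sq.counts["chd_events"]
            assert th.strategy_adverse_events > sq.strategy_adverse_events

    def test_duplicated_roster_preserves_means(self, roster_male, params, tables):
        single = cp.run_cohort(roster_male, "atp3", params, tables, seed=11)
        doubled = pd.concat([roster_male, roster_male], ignore_index=True)
        double = cp.run_cohort(doubled, "atp3", params, tables, seed=11)
        assert double.mean_qaly == pytest.approx(single.mean_qaly, rel=0.01)
        assert double.mean_cost == pytest.approx(single.mean_cost, rel=0.05)

    def test_null_treatment_matches_status_quo(self, roster_male, null_params,
                                               tables):
        base = cp.run_cohort(roster_male, "status_quo", null_params, tables,
                             seed=13)
        for name in ("atp3", "accaha", "jupiter", "shape", "texas",
                     "treat_all_high"):
            res = cp.run_cohort(roster_male, name, null_params, tables, seed=13)
            p_hat = base.counts["chd_events"] / base.n_simulated
            se = np.sqrt(2 * base.n_simulated * p_hat * (1 - p_hat))
            assert abs(res.counts["chd_events"]
                       - base.counts["chd_events"]) <= 3 * se, name

    def test_statin_disutility_monotone(self, roster_male, params, tables):
        qalys = [cp.run_cohort(roster_male, "treat_all_high", params, tables,
                               seed=15, statin_disutility_multiplier=m
                               ).qaly_discounted
                 for m in (1.0, 100.0, 1000.0)]
        assert qalys[0] > qalys[1] > qalys[2]

    def test_adverse_event_mode_annual_draws_more_events(self, roster_male,
                                                         params, tables):
        annual = params.copy()
        annual.set("adverse_event_mode", "annual")
        once = cp.run_cohort(roster_male, "treat_all_high", params, tables,
                             seed=17)
        ann = cp.run_cohort(roster_male, "treat_all_high", annual, tables,
                            seed=17)
        assert ann.counts["hepatitis"] > 5 * once.counts["hepatitis"]

    def test_empty_roster_rejected(self, params, tables, roster_male):
        with pytest.raises(ValueError):
            cp.run_cohort(roster_male.iloc[0:0], "atp3", params, tables)


class TestScaleToPopulation:
    def test_identity_and_factor(self, roster_male, params, tables):
        res = cp.run_cohort(roster_male, "atp3", params, tables, seed=19)
        same = scale_to_population(res, res.n_simulated)
        assert same.counts == res.counts
        scaled = scale_to_population(res, 46.9e6)
        f = 46.9e6 / res.n_simulated
        assert scaled.counts["chd_events"] == pytest.approx(
            res.counts["chd_events"] * f)
        assert scaled.mean_qaly == pytest.approx(res.mean_qaly)

    def test_rounding_mode_yields_integers(self, roster_male, params, tables):
        res = cp.run_cohort(roster_male, "atp3", params, tables, seed=19)
        scaled = scale_to_population(res, 12_345.0, rounding="round")
        assert all(float(v).is_integer() for v in scaled.counts.values())
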