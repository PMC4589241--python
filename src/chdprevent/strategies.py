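"""Treatment assignment for the eight primary-prevention strategies.

Each ``assign_*`` function maps a roster (or a single
:class:`~chdprevent.population.PersonProfile`) to a treatment plan: which
statin (if any), whether low-dose aspirin is given (men only), which tests
are performed and when, and — for calcium-score strategies — the outcome of
the nuclear-stress-test cascade triggered by CAC > 400.

Persons below a strategy's age window at entry (men < 50 / women < 60 for
the CAC- and CRP-based strategies) are treated by the LDL-goal approach in
the interim and risk-stratified once upon reaching the window age; there is
no repeat testing. Assignment is deterministic given (roster, strategy,
seed).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .population import PersonProfile, DistributionTables
from .risk import STATIN_NONE, STATIN_MODERATE, STATIN_HIGH, STATIN_ROSUVA

__all__ = [
    "PLAN_COLUMNS", "PceMap", "assign_atp3", "assign_accaha", "assign_jupiter",
    "assign_shape", "assign_texas", "assign_treat_all", "assign_status_quo",
    "shape_stress_cascade", "STRATEGIES", "assign",
]

#: LDL-C goals (mg/dl) under the goal-titration guideline, by FRS category.
ATP3_GOALS = {"0-5": 160.0, "5-10": 160.0, "10-15": 130.0, "15-20": 130.0, ">20": 100.0}

#: LDL-C goals by CAC category for the calcium-score strategies.
CAC_GOALS = {"0": 160.0, "1-100": 130.0, "101-400": 100.0,
             "401-1000": 70.0, ">1000": 70.0}

#: Strategy age windows (entry into risk stratification).
WINDOW_AGE = {"male": 50, "female": 60}

PLAN_COLUMNS = [
    "strategy", "statin0", "statin1", "switch_year", "ldl_goal", "aspirin",
    "cac_tested", "crp_tested", "test_year",
    "stress_test", "ischemia", "pci", "cabg", "revascularized",
]


class PceMap:
    """Piecewise-linear, monotone FRS -> Pooled-Cohort (ASCVD) risk map."""

    def __init__(self, table: pd.DataFrame):
        self._by_sex = {}
        for sex, grp in table.groupby("sex"):
            grp = grp.sort_values("frs")
            if not grp["pce"].is_monotonic_increasing:
                raise ValueError(f"PCE map not monotone for sex {sex!r}")
            self._by_sex[sex] = (grp["frs"].to_numpy(float), grp["pce"].to_numpy(float))

    def __call__(self, sex: str, frs10):
        x, y = self._by_sex[sex]
        return np.interp(np.asarray(frs10, float), x, y)


def _ensure_roster(profile):
    from .population import frs_category
    if isinstance(profile, PersonProfile):
        roster = pd.DataFrame([dataclasses.asdict(profile)])
        single = True
    else:
        roster = profile.reset_index(drop=True)
        single = False
    if "frs_cat" not in roster.columns:
        roster = roster.assign(frs_cat=frs_category(roster["frs10"].to_numpy()))
    return roster, single


def _empty_plan(n: int, strategy: str) -> pd.DataFrame:
    plan = pd.DataFrame({
        "strategy": strategy,
        "statin0": np.full(n, STATIN_NONE, dtype=object),
        "statin1": np.full(n, STATIN_NONE, dtype=object),
        "switch_year": np.zeros(n, dtype=np.int64),
        "ldl_goal": np.full(n, np.nan),
        "aspirin": np.zeros(n, dtype=bool),
        "cac_tested": np.zeros(n, dtype=bool),
        "crp_tested": np.zeros(n, dtype=bool),
        "test_year": np.zeros(n, dtype=np.int64),
        "stress_test": np.zeros(n, dtype=bool),
        "ischemia": np.zeros(n, dtype=bool),
        "pci": np.zeros(n, dtype=bool),
        "cabg": np.zeros(n, dtype=bool),
        "revascularized": np.zeros(n, dtype=bool),
    })
    return plan


def titrate_to_goal(ldl, goal, drop_moderate: float, drop_high: float):
    """Minimum statin intensity whose expected LDL drop reaches the goal.

    Persons already below goal stay untreated; if even the high-intensity
    expected drop cannot reach the goal, high intensity is given (best
    effort).
    """
    ldl = np.asarray(ldl, float)
    goal = np.asarray(goal, float)
    out = np.full(ldl.shape, STATIN_NONE, dtype=object)
    needs = ldl >= goal
    out[needs & (ldl * (1.0 - drop_moderate) < goal)] = STATIN_MODERATE
    out[needs & (ldl * (1.0 - drop_moderate) >= goal)] = STATIN_HIGH
    return out


def _frs_gated_aspirin(roster) -> np.ndarray:
    return ((roster["sex"] == "male") & (roster["frs10"] > 0.10)).to_numpy()


def _atp3_core(roster, params):
    goals = roster["frs_cat"].map(ATP3_GOALS).to_numpy(float)
    statin = titrate_to_goal(roster["ldl"].to_numpy(), goals,
                             params.get("statin.moderate.ldl_drop_fraction"),
                             params.get("statin.high.ldl_drop_fraction"))
    return statin, goals


def _finish(plan, single):
    return plan.iloc[0] if single else plan


def assign_atp3(profile, params, tables=None, seed: int = 0):
    """LDL-goal titration by FRS band (goals <160 / <130 / <100 mg/dl)."""
    roster, single = _ensure_roster(profile)
    plan = _empty_plan(len(roster), "atp3")
    statin, goals = _atp3_core(roster, params)
    plan["statin0"] = plan["statin1"] = statin
    plan["ldl_goal"] = goals
    plan["aspirin"] = _frs_gated_aspirin(roster)
    return _finish(plan, single)


def assign_accaha(profile, params, tables: DistributionTables,
                  seed: int = 0, moderate_5to7: bool = False):
    """2013 cholesterol-guideline rule on the Pooled Cohort (ASCVD) risk.

    High-intensity statin for LDL-C > 190 mg/dl regardless of risk; no
    statin below 70 mg/dl; otherwise high-intensity iff PCE >= 7.5%.  With
    ``moderate_5to7`` the sensitivity variant adds moderate-intensity statin
    at PCE 5-7.4%.
    """
    roster, single = _ensure_roster(profile)
    plan = _empty_plan(len(roster), "accaha")
    pce_map = PceMap(tables.pce_map)
    statin = np.full(len(roster), STATIN_NONE, dtype=object)
    ldl = roster["ldl"].to_numpy(float)
    for sex, grp in roster.groupby("sex"):
        idx = grp.index.to_numpy()
        pce = pce_map(sex, grp["frs10"].to_numpy())
        statin[idx[pce >= 0.075]] = STATIN_HIGH
        if moderate_5to7:
            statin[idx[(pce >= 0.05) & (pce < 0.075)]] = STATIN_MODERATE
    statin[ldl < 70.0] = STATIN_NONE
    statin[ldl > 190.0] = STATIN_HIGH
    plan["statin0"] = plan["statin1"] = statin
    plan["aspirin"] = _frs_gated_aspirin(roster)
    return _finish(plan, single)


def assign_jupiter(profile, params, tables=None, seed: int = 0):
    """CRP-based enrolment: rosuvastatin 20 mg for men >= 50 / women >= 60
    with LDL-C < 130 mg/dl and CRP > 2 mg/L; everyone else follows the
    LDL-goal (ATP III) rule. Persons younger than the window are tested once
    on reaching it."""
    roster, single = _ensure_roster(profile)
    plan = _empty_plan(len(roster), "jupiter")
    atp3_statin, goals = _atp3_core(roster, params)
    window = roster["sex"].map(WINDOW_AGE).to_numpy()
    test_year = np.maximum(0, window - roster["age_entry"].to_numpy()).astype(np.int64)
    included = ((roster["ldl"].to_numpy() < 130.0)
                & (roster["crp"].to_numpy() > 2.0))
    plan["crp_tested"] = True
    plan["test_year"] = test_year
    plan["switch_year"] = test_year
    statin1 = np.where(included, STATIN_ROSUVA, atp3_statin)
    statin0 = np.where(test_year == 0, statin1, atp3_statin)
    plan["statin0"], plan["statin1"] = statin0, statin1
    plan["ldl_goal"] = np.where(included, np.nan, goals)
    plan["aspirin"] = _frs_gated_aspirin(roster)
    return _finish(plan, single)


def assign_shape(profile, params, tables: DistributionTables, seed: int = 0):
    """Population CAC screening: men >= 50 / women >= 60 with >= 1 risk
    factor are calcium-scored and treated to the CAC-banded LDL goal; very
    low-risk persons (no risk factors) exit to the LDL-goal rule. CAC > 400
    triggers the nuclear-stress cascade."""
    roster, single = _ensure_roster(profile)
    plan = _empty_plan(len(roster), "shape")
    atp3_statin, atp3_goals = _atp3_core(roster, params)
    window = roster["sex"].map(WINDOW_AGE).to_numpy()
    test_year = np.maximum(0, window - roster["age_entry"].to_numpy()).astype(np.int64)
    tested = roster["n_shape_risk_factors"].to_numpy() >= 1
    return _cac_plan(plan, roster, params, tested, test_year,
                     atp3_statin, atp3_goals, seed, single)


def assign_texas(profile, params, tables: DistributionTables, seed: int = 0):
    """Hybrid rule: only persons with FRS > 10% are calcium-scored (same age
    window and CAC-banded goals as the screening strategy); FRS <= 10%
    follows the LDL-goal rule, so on an all-low-risk roster this strategy is
    identical to it."""
    roster, single = _ensure_roster(profile)
    plan = _empty_plan(len(roster), "texas")
    atp3_statin, atp3_goals = _atp3_core(roster, params)
    window = roster["sex"].map(WINDOW_AGE).to_numpy()
    test_year = np.maximum(0, window - roster["age_entry"].to_numpy()).astype(np.int64)
    tested = roster["frs10"].to_numpy() > 0.10
    return _cac_plan(plan, roster, params, tested, test_year,
                     atp3_statin, atp3_goals, seed, single)


def _cac_plan(plan, roster, params, tested, test_year, atp3_statin, atp3_goals,
              seed, single):
    cac_goal = roster["cac_category"].map(CAC_GOALS).to_numpy(float)
    goal = np.where(tested, cac_goal, atp3_goals)
    statin_cac = titrate_to_goal(roster["ldl"].to_numpy(), cac_goal,
                                 params.get("statin.moderate.ldl_drop_fraction"),
                                 params.get("statin.high.ldl_drop_fraction"))
    statin1 = np.where(tested, statin_cac, atp3_statin)
    statin0 = np.where(tested & (test_year > 0), atp3_statin, statin1)
    plan["cac_tested"] = tested
    plan["test_year"] = np.where(tested, test_year, 0)
    plan["switch_year"] = plan["test_year"]
    plan["statin0"], plan["statin1"] = statin0, statin1
    plan["ldl_goal"] = goal
    plan["aspirin"] = _frs_gated_aspirin(roster)
    high_cac = tested & roster["cac_category"].isin(["401-1000", ">1000"]).to_numpy()
    cascade = shape_stress_cascade(high_cac, params, seed)
    for k, v in cascade.items():
        plan[k] = v
    return _finish(plan, single)


def assign_treat_all(profile, params=None, tables=None, seed: int = 0,
                     intensity: str = STATIN_HIGH):
    """Statin for everyone at the given intensity; aspirin for all men."""
    if intensity not in (STATIN_MODERATE, STATIN_HIGH):
        raise ValueError(f"treat-all intensity must be moderate or high, got {intensity!r}")
    roster, single = _ensure_roster(profile)
    plan = _empty_plan(len(roster), f"treat_all_{intensity}")
    plan["statin0"] = plan["statin1"] = intensity
    plan["aspirin"] = (roster["sex"] == "male").to_numpy()
    return _finish(plan, single)


def assign_status_quo(profile, params, tables: DistributionTables, seed: int = 0):
    """Comparator arm: Bernoulli moderate-dose statin and aspirin use at the
    observed age/sex rates."""
    roster, single = _ensure_roster(profile)
    plan = _empty_plan(len(roster), "status_quo")
    rng = np.random.default_rng(np.random.Philox(key=(seed << 8) + 11))
    statin = np.full(len(roster), STATIN_NONE, dtype=object)
    aspirin = np.zeros(len(roster), dtype=bool)
    for sex, grp in roster.groupby("sex"):
        ages = grp["age_entry"].to_numpy()
        idx = grp.index.to_numpy()
        s_rate = tables.band_lookup(tables.status_quo_use, sex, ages, "statin_rate")
        a_rate = tables.band_lookup(tables.status_quo_use, sex, ages, "aspirin_rate")
        statin[idx[rng.random(len(grp)) < s_rate]] = STATIN_MODERATE
        aspirin[idx] = rng.random(len(grp)) < a_rate
    aspirin &= (roster["sex"] == "male").to_numpy()
    plan["statin0"] = plan["statin1"] = statin
    plan["aspirin"] = aspirin
    return _finish(plan, single)


def shape_stress_cascade(high_cac_mask, params, seed: int = 0) -> dict:
    """Resolve the diagnostic cascade for persons with CAC > 400.

    Every such person undergoes nuclear stress testing; with the configured
    probability the test shows moderate/severe (>10% myocardium) reversible
    ischemia, leading to coronary angiography and, for the configured
    fractions, PCI or CABG. Costs, disutilities and post-cascade risks are
    applied by the simulation engine at the year of testing. A negative
    stress test leaves the person on the <70 mg/dl LDL goal.
    """
    mask = np.asarray(high_cac_mask, bool)
    n = mask.shape[0]
    rng = np.random.default_rng(np.random.Philox(key=(seed << 8) + 13))
    u_isch = rng.random(n)
    u_revasc = rng.random(n)
    p_isch = params.get("stress_cascade.p_moderate_severe_ischemia")
    p_pci = params.get("stress_cascade.p_pci")
    p_cabg = params.get("stress_cascade.p_cabg")
    ischemia = mask & (u_isch < p_isch)
    pci = ischemia & (u_revasc < p_pci)
    cabg = ischemia & (u_revasc >= p_pci) & (u_revasc < p_pci + p_cabg)
    return {
        "stress_test": mask,
        "ischemia": ischemia,
        "pci": pci,
        "cabg": cabg,
        "revascularized": pci | cabg,
    }


def _treat_all_factory(intensity):
    def _assign(profile, params=None, tables=None, seed: int = 0):
        return assign_treat_all(profile, params, tables, seed, intensity=intensity)
    return _assign


#: Strategy registry: name -> assign(roster, params, tables, seed) -> plan.
STRATEGIES = {
    "status_quo": assign_status_quo,
    "atp3": assign_atp3,
    "accaha": assign_accaha,
    "jupiter": assign_jupiter,
    "shape": assign_shape,
    "texas": assign_texas,
    "treat_all_moderate": _treat_all_factory(STATIN_MODERATE),
    "treat_all_high": _treat_all_factory(STATIN_HIGH),
}


def assign(strategy: str, roster, params, tables, seed: int = 0, **kwargs):
    """Assign a strategy by name (see :data:`STRATEGIES`)."""
    if strategy not in STRATEGIES:
        raise KeyError(f"unknown strategy {strategy!r}; choose from {sorted(STRATEGIES)}")
    return STRATEGIES[strategy](roster, params, tables, seed=seed, **kwargs)
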