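"""Annual-cycle state-transition microsimulation.

Runs a roster under one strategy's treatment plan for up to 30 annual
cycles, tracking a four-state structure (alive without CHD, alive post-MI,
CHD death, non-CHD death) plus persistent flags (post hemorrhagic stroke,
statin-related diabetes, radiation-attributable cancer, revascularisation),
and accruing discounted costs and quality-adjusted life years.

Within a cycle the order of operations is: non-CHD death, CHD event (fatal
with a configurable case fatality), then medication harms; persons accrue
nothing in the year they die and no half-cycle correction is applied.
Random numbers come from counter-based generators in a fixed draw order, so
results are independent of iteration order and identical draws are shared
across strategies run with the same seed (common random numbers).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .population import DistributionTables
from .risk import (RiskParameters, STATIN_NONE, STATIN_MODERATE, STATIN_HIGH,
                   STATIN_ROSUVA, annual_chd_probability,
                   rebase_relative_risk, statin_relative_risk,
                   aspirin_relative_risk)
from .strategies import assign

__all__ = ["CohortResult", "run_cohort", "scale_to_population",
            "apply_medication_adverse_events", "apply_radiation_risk"]

_AE_TYPES = ("hepatitis", "liver_failure", "myopathy", "rhabdomyolysis", "diabetes")
_CANCERS = ("lung", "breast", "leukemia")

COUNT_FIELDS = [
    "chd_events", "nonfatal_mi", "fatal_mi", "deaths_chd", "deaths_other",
    "gi_bleeds", "hemorrhagic_strokes",
    "hepatitis", "liver_failure", "myopathy", "rhabdomyolysis", "diabetes",
    "cancers_lung", "cancers_breast", "cancers_leukemia", "cancers_stress",
    "cac_scans", "crp_tests", "stress_tests", "angiographies", "pci", "cabg",
    "on_statin", "on_aspirin",
]


@dataclasses.dataclass
class CohortResult:
    """Per-strategy tallies from one simulated cohort."""

    strategy: str
    n_simulated: float
    horizon: int
    counts: dict
    cost_discounted: float
    qaly_discounted: float
    qaly_undiscounted: float
    life_years: float

    def __post_init__(self):
        if any(v < -1e-9 for v in self.counts.values()):
            raise ValueError("negative tally")
        if self.qaly_discounted > self.qaly_undiscounted + 1e-6:
            raise ValueError("discounted QALYs exceed undiscounted")
        if self.qaly_undiscounted > self.life_years + 1e-6:
            raise ValueError("QALYs exceed life-years")

    @property
    def deaths_total(self) -> float:
        return self.counts["deaths_chd"] + self.counts["deaths_other"]

    @property
    def cancers_total(self) -> float:
        return (self.counts["cancers_lung"] + self.counts["cancers_breast"]
                + self.counts["cancers_leukemia"] + self.counts["cancers_stress"])

    @property
    def strategy_adverse_events(self) -> float:
        """Strategy-related adverse events: statin harms, incident diabetes
        and radiation-attributable cancers."""
        c = self.counts
        return (c["myopathy"] + c["rhabdomyolysis"] + c["hepatitis"]
                + c["liver_failure"] + c["diabetes"] + self.cancers_total)

    @property
    def mean_cost(self) -> float:
        return self.cost_discounted / self.n_simulated

    @property
    def mean_qaly(self) -> float:
        return self.qaly_discounted / self.n_simulated

    def per_person(self) -> dict:
        out = {k: v / self.n_simulated for k, v in self.counts.items()}
        out.update(mean_cost=self.mean_cost, mean_qaly=self.mean_qaly,
                   mean_life_years=self.life_years / self.n_simulated)
        return out

    def to_series(self) -> pd.Series:
        d = {"strategy": self.strategy, "n": self.n_simulated, **self.counts,
             "deaths_total": self.deaths_total, "cancers_total": self.cancers_total,
             "cost_discounted": self.cost_discounted,
             "qaly_discounted": self.qaly_discounted,
             "qaly_undiscounted": self.qaly_undiscounted,
             "life_years": self.life_years}
        return pd.Series(d)


def scale_to_population(result: CohortResult, population_size: float,
                        rounding: str | None = None) -> CohortResult:
    """Extrapolate cohort tallies to population scale.

    Every count and accumulator is multiplied by
    ``population_size / n_simulated``; ``rounding="round"`` returns integer
    counts.
    """
    if result.n_simulated < 1:
        raise ValueError("result has no simulated persons")
    f = population_size / result.n_simulated
    counts = {k: v * f for k, v in result.counts.items()}
    if rounding == "round":
        counts = {k: float(np.round(v)) for k, v in counts.items()}
    return CohortResult(
        strategy=result.strategy, n_simulated=population_size,
        horizon=result.horizon, counts=counts,
        cost_discounted=result.cost_discounted * f,
        qaly_discounted=result.qaly_discounted * f,
        qaly_undiscounted=result.qaly_undiscounted * f,
        life_years=result.life_years * f)


def _statin_block(params, intensity: str):
    key = {STATIN_MODERATE: "statin.moderate", STATIN_HIGH: "statin.high",
           STATIN_ROSUVA: "statin.rosuvastatin"}[intensity]
    return key


def _ae_incidence(params, intensity, ae):
    if intensity == STATIN_NONE:
        return 0.0
    return params.get(f"{_statin_block(params, intensity)}.adverse_events.{ae}.incidence")


def apply_medication_adverse_events(statin0, statin1, switch_year, params, rng,
                                    mode: str = "once"):
    """Draw statin-associated adverse events for each initiator.

    In ``once`` mode a single uniform per person per event type is compared
    against the initiation incidence of the intensity being started; a later
    escalation to a higher intensity re-uses the same uniform, so only the
    incremental probability can trigger a (single) event at the escalation
    year. Returns ``{event_type: event_year}`` arrays (-1 where no event).
    """
    statin0 = np.asarray(statin0, object)
    statin1 = np.asarray(statin1, object)
    switch_year = np.asarray(switch_year)
    n = len(statin0)
    years = {}
    for ae in _AE_TYPES:
        u = rng.random(n)
        inc0 = np.array([_ae_incidence(params, s, ae) for s in
                         (STATIN_NONE, STATIN_MODERATE, STATIN_HIGH, STATIN_ROSUVA)])
        code = {STATIN_NONE: 0, STATIN_MODERATE: 1, STATIN_HIGH: 2, STATIN_ROSUVA: 3}
        i0 = inc0[[code[s] for s in statin0]]
        i1 = inc0[[code[s] for s in statin1]]
        year = np.full(n, -1, dtype=np.int64)
        at_entry = u < i0
        year[at_entry] = 0
        at_switch = (~at_entry) & (u < i1) & (switch_year > 0)
        year[at_switch] = switch_year[at_switch]
        years[ae] = year
    return years


def apply_radiation_risk(ages_at_scan, sex, n_scans, dose_msv, params, tables, rng):
    """Schedule radiation-attributable cancers from CAC scanning.

    Per scan, each cancer type is drawn with its per-sex risk anchored at
    the published exposure age, scaled linearly in effective dose relative
    to the reference protocol and mildly declining with exposure age; onset
    is lagged (solid tumours 10 y, leukemia 2 y). Returns
    ``{cancer: onset_year}`` arrays (-1 where none), relative to scan year 0.
    """
    if dose_msv < 0:
        raise ValueError("radiation dose must be nonnegative")
    ages = np.asarray(ages_at_scan, float)
    n = len(ages)
    n_scans = np.broadcast_to(np.asarray(n_scans), (n,))
    sex = np.broadcast_to(np.asarray(sex, object), (n,))
    ref = params.get("radiation.reference_dose_msv")
    lag_solid = params.get("radiation.lag_years.solid")
    lag_leuk = params.get("radiation.lag_years.leukemia")
    tab = tables.radiation_risk
    onsets = {}
    for cancer in _CANCERS:
        p = np.zeros(n)
        for sx in ("male", "female"):
            row = tab[(tab["sex"] == sx) & (tab["cancer"] == cancer)]
            if row.empty:
                continue
            base = float(row["risk_per_100k"].iloc[0]) / 1e5
            anchor = float(row["anchor_age"].iloc[0])
            m = sex == sx
            age_factor = np.clip(1.0 - 0.02 * (ages[m] - anchor), 0.3, 1.3)
            p[m] = base * age_factor * (dose_msv / ref)
        p = np.clip(p * n_scans, 0.0, 1.0)
        hit = rng.random(n) < p
        lag = lag_leuk if cancer == "leukemia" else lag_solid
        year = np.full(n, -1, dtype=np.int64)
        year[hit] = lag
        onsets[cancer] = year
    return onsets


def _other_cause_survival(roster, tables, horizon) -> np.ndarray:
    """Survival through non-CHD mortality, per person, to the start of each
    cycle (shape ``(n, horizon)``)."""
    n = len(roster)
    surv = np.ones((n, max(horizon, 1)))
    for sex, grp in roster.groupby("sex"):
        idx = grp.index.to_numpy()
        ages = grp["age_entry"].to_numpy()
        alive = np.ones(len(idx))
        for t in range(1, horizon):
            q = tables.mortality_lookup(sex, ages + t - 1)
            alive = alive * (1.0 - q)
            surv[idx, t] = alive
    return surv


def _expected_first_events(p, surv) -> float:
    """Expected first CHD events over the horizon given annual probability
    ``p`` and other-cause survival ``surv`` (n, horizon)."""
    horizon = surv.shape[1]
    t = np.arange(horizon)
    no_event = (1.0 - p)[:, None] ** t[None, :]
    return float((surv * no_event * p[:, None]).sum())


def _strat_rr(roster, plan, params, tables, horizon):
    """Stratification relative risk (CAC or CRP) applied to tested persons.

    Within each (sex, 10-y age band, FRS category) stratum the relative
    risks are divided by a normalising constant chosen so that the
    stratum's expected number of first CHD events over the whole horizon
    (accounting for background mortality) is unchanged: measuring a marker
    redistributes risk without inflating it. The annual-scale cohort mean is
    the starting point for the root solve.
    """
    n = len(roster)
    rr = np.ones(n)
    p_base = annual_chd_probability(roster["frs10"].to_numpy())
    tested = plan["cac_tested"].to_numpy() | plan["crp_tested"].to_numpy()
    if not tested.any():
        return rr
    if plan["cac_tested"].any():
        cac_rr_map = {k: float(v) for k, v in params.get("cac.rr_by_category").items()}
        m = plan["cac_tested"].to_numpy()
        rr[m] = roster.loc[m, "cac_category"].map(cac_rr_map).to_numpy(float)
    if plan["crp_tested"].any():
        m = plan["crp_tested"].to_numpy()
        crp = roster.loc[m, "crp"].to_numpy(float)
        lowfrs = roster.loc[m, "frs10"].to_numpy() < 0.10
        bands = np.digitize(crp, [0.5, 1.0, 3.0, 10.0])
        table_lt = params.get("crp_rr.frs_lt10")
        table_ge = params.get("crp_rr.frs_ge10")
        vals_lt = np.array([table_lt[k] for k in ("<0.5", "0.5-1", "1-3", "3-10", ">10")])
        vals_ge = np.array([table_ge[k] for k in ("<0.5", "0.5-1", "1-3", "3-10", ">10")])
        rr[m] = np.where(lowfrs, vals_lt[bands], vals_ge[bands])
    strata = (roster["sex"].astype(str) + "|"
              + (roster["age_entry"] // 10 * 10).astype(str) + "|"
              + roster["frs_cat"].astype(str)).to_numpy()
    surv = _other_cause_survival(roster, tables, horizon)
    out = np.ones(n)
    from scipy.optimize import brentq
    for s in np.unique(strata[tested]):
        m = tested & (strata == s)
        p_s, rr_s, surv_s = p_base[m], rr[m], surv[m]
        target = _expected_first_events(p_s, surv_s)
        if target <= 0 or np.ptp(rr_s) == 0:
            out[m] = 1.0
            continue

        def gap(divisor):
            p_new = np.clip(p_s * rr_s / divisor, 0.0, 1.0)
            return _expected_first_events(p_new, surv_s) - target

        lo, hi = rr_s.min() * 0.5, rr_s.max() * 2.0
        divisor = brentq(gap, lo, hi, xtol=1e-12)
        out[m] = rebase_relative_risk(p_s, rr_s, divisor) / p_s
    return out


def run_cohort(roster: pd.DataFrame, strategy, params, tables: DistributionTables,
               horizon: int = 30, seed: int = 0, adherence: float | None = None,
               cac_adherence: dict | None = None,
               statin_disutility_multiplier: float = 1.0) -> CohortResult:
    """Simulate a roster under one strategy and tally outcomes.

    ``strategy`` is a registry name or an already-assigned plan DataFrame.
    ``adherence`` overrides the global medication-adherence probability;
    ``cac_adherence`` maps CAC categories to adherence probabilities for
    calcium-score-aware scenarios; ``statin_disutility_multiplier`` scales
    the per-year statin disutility (sensitivity analyses).
    """
    if len(roster) == 0:
        raise ValueError("roster is empty")
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    roster = roster.reset_index(drop=True)
    if isinstance(strategy, str):
        plan = assign(strategy, roster, params, tables, seed=seed)
    else:
        plan = strategy.reset_index(drop=True)
    name = plan["strategy"].iloc[0]
    n = len(roster)
    rp = RiskParameters.from_params(params)
    rng_once = np.random.default_rng(np.random.Philox(key=(seed << 8) + 2))
    rng_year = np.random.default_rng(np.random.Philox(key=(seed << 8) + 1))

    sexes = roster["sex"].to_numpy(object)
    age_entry = roster["age_entry"].to_numpy(np.int64)
    p_base = annual_chd_probability(roster["frs10"].to_numpy())
    strat_rr = _strat_rr(roster, plan, params, tables, horizon)
    low_risk = roster["frs10"].to_numpy() < rp.low_risk_frs_threshold
    statin0 = plan["statin0"].to_numpy(object)
    statin1 = plan["statin1"].to_numpy(object)
    switch_year = plan["switch_year"].to_numpy(np.int64)
    test_year = plan["test_year"].to_numpy(np.int64)
    rr_statin0 = statin_relative_risk(roster["ldl"].to_numpy(), statin0, rp, low_risk)
    rr_statin1 = statin_relative_risk(roster["ldl"].to_numpy(), statin1, rp, low_risk)
    aspirin = plan["aspirin"].to_numpy(bool)
    rr_aspirin = aspirin_relative_risk(sexes, aspirin, rp)

    # Persistent per-person adherence (single draw at therapy start).
    if cac_adherence is not None:
        adh_p = np.full(n, adherence if adherence is not None else rp.adherence)
        cac_aware = plan["cac_tested"].to_numpy(bool)
        adh_p[cac_aware] = roster.loc[cac_aware, "cac_category"].map(
            cac_adherence).to_numpy(float)
    else:
        adh_p = np.full(n, adherence if adherence is not None else rp.adherence)
    adherent = rng_once.random(n) < adh_p

    # One-time statin initiation adverse events (all initiators; harms from
    # early exposure precede any discontinuation).
    ae_mode = params.get("adverse_event_mode")
    if ae_mode not in ("once", "annual"):
        raise ValueError(f"adverse_event_mode must be 'once' or 'annual', got {ae_mode!r}")
    if ae_mode == "once":
        ae_year = apply_medication_adverse_events(statin0, statin1, switch_year,
                                                  params, rng_once)
    else:
        ae_year = {ae: np.full(n, -1, dtype=np.int64) for ae in _AE_TYPES}

    # Radiation-attributable cancers, scheduled relative to the scan year.
    cac_tested = plan["cac_tested"].to_numpy(bool)
    dose = params.get("cac.effective_dose_msv")
    onset_rel = apply_radiation_risk(age_entry + test_year, sexes,
                                     cac_tested.astype(int), dose, params,
                                     tables, rng_once)
    cancer_onset = {c: np.where(y >= 0, test_year + y, -1)
                    for c, y in onset_rel.items()}
    # Nuclear-stress-test radiation cancer (solid-tumour lag).
    stress = plan["stress_test"].to_numpy(bool)
    u_stress_ca = rng_once.random(n)
    stress_ca_year = np.where(
        stress & (u_stress_ca < params.get("stress_cascade.stress_test.cancer_risk")),
        test_year + params.get("radiation.lag_years.solid"), -1)

    ischemia = plan["ischemia"].to_numpy(bool)
    revasc = plan["revascularized"].to_numpy(bool)

    disc = (1.0 + params.get("discount_rate")) ** (-np.arange(max(horizon, 1)))
    case_fatality = params.get("mi_case_fatality")
    mi_cost_up = params.get("mi.cost_upfront")
    mi_cost_ann = params.get("mi.cost_annual")
    u_mi_first = params.get("mi.utility_first_8_days")
    u_mi_ann = params.get("mi.utility_annual")
    mi_year_utility = (8 * u_mi_first + 357 * u_mi_ann) / 365.0
    care_cost = (params.get("statin_care_annual_cost.physician_visits")
                 + params.get("statin_care_annual_cost.laboratory"))
    gi_inc = params.get("aspirin.gi_bleed.annual_incidence")
    hs_inc = params.get("aspirin.hemorrhagic_stroke.annual_incidence")
    intol_exp = (params.get("statin.intolerance.incidence")
                 * params.get("statin.intolerance.qaly_decrement"))
    drug_cost = {
        STATIN_NONE: 0.0,
        STATIN_MODERATE: params.get("statin.moderate.annual_cost"),
        STATIN_HIGH: params.get("statin.high.annual_cost"),
    }
    disut = {
        STATIN_NONE: 0.0,
        STATIN_MODERATE: params.get("statin.moderate.disutility"),
        STATIN_HIGH: params.get("statin.high.disutility"),
        STATIN_ROSUVA: params.get("statin.rosuvastatin.disutility"),
    }
    rosuva_generic_from = params.get("statin.rosuvastatin.generic_from_year")
    rosuva_costs = (params.get("statin.rosuvastatin.annual_cost"),
                    params.get("statin.rosuvastatin.annual_cost_generic"))
    ae_cost = {ae: params.get(f"statin.high.adverse_events.{ae}.cost")
               for ae in _AE_TYPES}
    ae_dec = {ae: params.get(f"statin.high.adverse_events.{ae}.qaly_decrement")
              for ae in _AE_TYPES}
    mort = {sx: None for sx in ("male", "female")}
    all_ages = np.arange(0, 121)
    for sx in mort:
        mort[sx] = tables.mortality_lookup(sx, all_ages)
    statin_dec0 = np.array([disut[s] for s in statin0])
    statin_dec1 = np.array([disut[s] for s in statin1])
    _code = {STATIN_NONE: 0, STATIN_MODERATE: 1, STATIN_HIGH: 2, STATIN_ROSUVA: 3}
    code0 = np.array([_code[s] for s in statin0], dtype=np.int8)
    code1 = np.array([_code[s] for s in statin1], dtype=np.int8)
    cost_by_code = np.array([0.0, drug_cost[STATIN_MODERATE],
                             drug_cost[STATIN_HIGH], 0.0])

    alive = np.ones(n, dtype=bool)
    dead_chd = np.zeros(n, dtype=bool)
    post_mi = np.zeros(n, dtype=bool)
    mi_year = np.full(n, -1, dtype=np.int64)
    stroke_flag = np.zeros(n, dtype=bool)
    diab_year = np.full(n, horizon + 1, dtype=np.int64)
    if ae_mode == "once":
        dy = ae_year["diabetes"]
        diab_year = np.where(dy >= 0, dy, horizon + 1)

    counts = {k: 0.0 for k in COUNT_FIELDS}
    counts["on_statin"] = float(((statin0 != STATIN_NONE)
                                 | (statin1 != STATIN_NONE)).sum())
    counts["on_aspirin"] = float(aspirin.sum())
    cost_total = 0.0
    qaly_disc = 0.0
    qaly_undisc = 0.0
    life_years = 0.0
    is_male = sexes == "male"
    male_idx = mort["male"]
    female_idx = mort["female"]

    cascade_p = {k: params.get(f"stress_cascade.{k}") for k in
                 ("ischemia_annual_mortality", "ischemia_annual_mi",
                  "revasc_mortality_reduction", "revasc_mi_reduction")}
    isch_mi = np.where(revasc, cascade_p["ischemia_annual_mi"]
                       - cascade_p["revasc_mi_reduction"],
                       cascade_p["ischemia_annual_mi"])
    isch_mort = np.where(revasc, cascade_p["ischemia_annual_mortality"]
                         - cascade_p["revasc_mortality_reduction"],
                         cascade_p["ischemia_annual_mortality"])

    for t in range(horizon):
        u_death = rng_year.random(n)
        u_chd = rng_year.random(n)
        u_fatal = rng_year.random(n)
        u_gi = rng_year.random(n)
        u_stroke = rng_year.random(n)
        u_extra = rng_year.random(n)

        age = age_entry + t
        q_other = np.where(is_male, male_idx[np.clip(age, 0, 120)],
                           female_idx[np.clip(age, 0, 120)])
        start_alive = alive.copy()
        die_other = start_alive & (u_death < q_other)

        # Current statin phase and treatment effect.
        phase1 = t >= switch_year
        statin_code_now = np.where(phase1, code1, code0)
        rr_statin_now = np.where(phase1, rr_statin1, rr_statin0)
        on_statin_now = statin_code_now != 0
        eff_statin = np.where(adherent, rr_statin_now, 1.0)
        eff_aspirin = np.where(adherent, rr_aspirin, 1.0)
        p_chd = np.clip(p_base * strat_rr * eff_statin * eff_aspirin, 0.0, 1.0)
        isch_active = ischemia & (t >= test_year)
        p_chd = np.where(isch_active, isch_mi, p_chd)

        at_risk = start_alive & ~die_other & ~post_mi
        event = at_risk & (u_chd < p_chd)
        fatal = event & (u_fatal < case_fatality)
        nonfatal = event & ~fatal

        die_isch = (start_alive & ~die_other & ~fatal & isch_active
                    & (u_extra < isch_mort))

        died_now = die_other | fatal | die_isch
        alive_end = start_alive & ~died_now

        post_mi = post_mi | (nonfatal & alive_end)
        mi_year[nonfatal & alive_end] = t
        dead_chd |= (fatal | die_isch)
        alive = alive_end

        counts["deaths_other"] += float(die_other.sum())
        counts["deaths_chd"] += float((fatal | die_isch).sum())
        counts["chd_events"] += float(event.sum())
        counts["fatal_mi"] += float(fatal.sum())
        counts["nonfatal_mi"] += float(nonfatal[alive_end].sum())

        # Aspirin harms while on therapy.
        on_aspirin_now = aspirin & adherent & alive_end
        gi = on_aspirin_now & (u_gi < gi_inc)
        new_stroke = on_aspirin_now & (u_stroke < hs_inc) & ~stroke_flag
        stroke_flag |= new_stroke
        counts["gi_bleeds"] += float(gi.sum())
        counts["hemorrhagic_strokes"] += float(new_stroke.sum())

        year_cost = np.zeros(n)
        year_dec = np.zeros(n)
        util_mult = np.ones(n)

        if ae_mode == "annual":
            inc_by_code = {
                ae: np.array([0.0,
                              _ae_incidence(params, STATIN_MODERATE, ae),
                              _ae_incidence(params, STATIN_HIGH, ae),
                              _ae_incidence(params, STATIN_ROSUVA, ae)])
                for ae in _AE_TYPES}
            for ae in _AE_TYPES:
                u = rng_year.random(n)
                inc = inc_by_code[ae][statin_code_now]
                hit = alive_end & adherent & on_statin_now & (u < inc)
                if ae == "diabetes":
                    hit &= diab_year > horizon
                    diab_year[hit] = t
                ae_year[ae][hit & (ae_year[ae] < 0)] = t
                counts[ae] += float(hit.sum())
                year_cost[hit] += ae_cost[ae]
                year_dec[hit] += ae_dec[ae]
        else:
            for ae in _AE_TYPES:
                hit = alive_end & (ae_year[ae] == t)
                counts[ae] += float(hit.sum())
                year_cost[hit] += ae_cost[ae]
                year_dec[hit] += ae_dec[ae]

        # Tests, cascade and their one-time costs at the testing year.
        newly_tested = alive_end & (test_year == t)
        ct = newly_tested & cac_tested
        counts["cac_scans"] += float(ct.sum())
        year_cost[ct] += params.get("cac.cost")
        crpt = newly_tested & plan["crp_tested"].to_numpy(bool)
        counts["crp_tests"] += float(crpt.sum())
        year_cost[crpt] += params.get("crp_test_cost")
        st = newly_tested & stress
        counts["stress_tests"] += float(st.sum())
        year_cost[st] += params.get("stress_cascade.stress_test.cost")
        year_dec[st] += params.get("stress_cascade.stress_test.qaly_decrement")
        ang = newly_tested & ischemia
        counts["angiographies"] += float(ang.sum())
        year_cost[ang] += params.get("stress_cascade.angiography_cost")
        pci_now = newly_tested & plan["pci"].to_numpy(bool)
        counts["pci"] += float(pci_now.sum())
        year_cost[pci_now] += params.get("stress_cascade.pci.cost")
        year_dec[pci_now] += params.get("stress_cascade.pci.qaly_decrement")
        cabg_now = newly_tested & plan["cabg"].to_numpy(bool)
        counts["cabg"] += float(cabg_now.sum())
        year_cost[cabg_now] += params.get("stress_cascade.cabg.cost")
        year_dec[cabg_now] += params.get("stress_cascade.cabg.qaly_decrement")

        # Radiation-attributable cancer onsets.
        for cancer in _CANCERS:
            onset = cancer_onset[cancer]
            new = alive_end & (onset == t)
            counts[f"cancers_{cancer}"] += float(new.sum())
            year_cost[new] += params.get(f"radiation.cancers.{cancer}.cost")
            active = alive_end & (onset >= 0) & (onset <= t)
            if active.any():
                first = params.get(f"radiation.cancers.{cancer}.utility_first_year")
                later = params.get(f"radiation.cancers.{cancer}.utility_later")
                phase_years = params.get(f"radiation.cancers.{cancer}.first_phase_years")
                mult = np.where(t - onset < phase_years, first, later)
                util_mult[active] = np.minimum(util_mult[active], mult[active])
        new_sca = alive_end & (stress_ca_year == t)
        counts["cancers_stress"] += float(new_sca.sum())
        year_cost[new_sca] += params.get("stress_cascade.stress_test.cancer_cost")
        year_dec[new_sca] += params.get("stress_cascade.stress_test.cancer_qaly_lost")

        # Aspirin harm costs/decrements.
        year_cost[gi] += params.get("aspirin.gi_bleed.cost")
        year_dec[gi] += params.get("aspirin.gi_bleed.qaly_decrement")
        year_cost[new_stroke] += params.get("aspirin.hemorrhagic_stroke.cost")
        year_dec[stroke_flag & alive_end] += params.get(
            "aspirin.hemorrhagic_stroke.qaly_decrement")

        # Ongoing therapy costs and disutility (adherent persons only).
        on_therapy = alive_end & adherent & on_statin_now
        rosuva_now = on_therapy & (statin_code_now == 3)
        year_cost[on_therapy] += cost_by_code[statin_code_now[on_therapy]]
        year_cost[rosuva_now] += (rosuva_costs[0] if t < rosuva_generic_from
                                  else rosuva_costs[1])
        year_cost[on_therapy] += care_cost
        statin_dec = np.where(phase1, statin_dec1, statin_dec0)
        year_dec[on_therapy] += (statin_dec[on_therapy] + intol_exp) \
            * statin_disutility_multiplier
        asp_now = aspirin & adherent & alive_end
        year_cost[asp_now] += params.get("aspirin.annual_cost")

        # Diabetes: lifelong utility decrement from the event year on.
        diab_active = alive_end & (diab_year <= t)
        year_dec[diab_active] += params.get(
            "statin.high.adverse_events.diabetes.qaly_decrement")
        # (the one-time diabetes episode cost was added with the event above)

        # Post-MI state costs.
        mi_now = alive_end & post_mi & (mi_year == t)
        year_cost[mi_now] += mi_cost_up
        mi_later = alive_end & post_mi & (mi_year < t)
        year_cost[mi_later] += mi_cost_ann

        # Utilities.
        base_util = np.ones(n)
        base_util[mi_later] = u_mi_ann
        base_util[mi_now] = mi_year_utility
        util = np.clip(base_util * util_mult - year_dec, 0.0, 1.0)

        qaly_disc += float(util[alive_end].sum()) * disc[t]
        qaly_undisc += float(util[alive_end].sum())
        life_years += float(alive_end.sum())
        cost_total += float(year_cost[alive_end].sum()) * disc[t]

        # Occupancy conservation across states.
        assert int(alive.sum() + dead_chd.sum()
                   + counts["deaths_other"]) == n

    return CohortResult(strategy=name, n_simulated=float(n), horizon=horizon,
                        counts=counts, cost_discounted=cost_total,
                        qaly_discounted=qaly_disc, qaly_undiscounted=qaly_undisc,
                        life_years=life_years)
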