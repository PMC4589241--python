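import pytest

import chdprevent as cp

SEED = 1
N_SMALL = 4000
N_BASE = 40_000  # basecase cohort size per sex for the headline comparisons


@pytest.fixture(scope="session")
def tables():
    return cp.default_tables()


@pytest.fixture(scope="session")
def params():
    return cp.default_parameters()


@pytest.fixture(scope="session")
def roster_male(tables):
    return cp.sample_cohort(N_SMALL, "male", tables, seed=SEED)


@pytest.fixture(scope="session")
def roster_female(tables):
    return cp.sample_cohort(N_SMALL, "female", tables, seed=SEED)


@pytest.fixture(scope="session")
def basecase(tables, params):
    """All eight strategies for both sexes on common rosters (shared by the
    acceptance and directional tests)."""
    cfg = cp.RunConfig(n_per_sex=N_BASE, seed=SEED)
    return cp.run_all_strategies(cfg, params, tables)


@pytest.fixture()
def null_params(params):
    """Parameter set with every treatment effect and harm switched off."""
    p = params.copy()
    p.set("statin.moderate.ldl_drop_fraction", 0.0)
    p.set("statin.high.ldl_drop_fraction", 0.0)
    p.set("statin.rosuvastatin.ldl_drop_mg", 0.0)
    p.set("aspirin.rr_chd_male", 1.0)
    p.set("aspirin.gi_bleed.annual_incidence", 0.0)
    p.set("aspirin.hemorrhagic_stroke.annual_incidence", 0.0)
    for block in ("moderate", "high", "rosuvastatin"):
        for ae in ("hepatitis", "liver_failure", "myopathy", "rhabdomyolysis",
                   "diabetes"):
            p.set(f"statin.{block}.adverse_events.{ae}.incidence", 0.0)
    p.set("stress_cascade.stress_test.cancer_risk", 0.0)
    # the stress cascade replaces FRS-based risks for CAC>400 persons; a
    # true null model must switch that pathway off as well
    p.set("stress_cascade.p_moderate_severe_ischemia", 0.0)
    return p


def make_profile(**kw):
    base = dict(id=0, sex="male", age_entry=55, frs10=0.08, ldl=120.0,
                cac_category="0", crp=1.0, n_shape_risk_factors=1)
    base.update(kw)
    return cp.PersonProfile(**base)


def zero_counts():
    from chdprevent.microsim import COUNT_FIELDS
    return {k: 0.0 for k in COUNT_FIELDS}


def make_result(strategy="x", n=1000.0, **overrides):
    counts = zero_counts()
    counts.update({k: v for k, v in overrides.items() if k in counts})
    other = {k: v for k, v in overrides.items() if k not in counts}
    from chdprevent.microsim import CohortResult
    return CohortResult(strategy=strategy, n_simulated=n, horizon=30,
                        counts=counts,
                        cost_discounted=other.get("cost", 0.0),
                        qaly_discounted=other.get("qaly", 0.0),
                        qaly_undiscounted=other.get("qaly", 0.0),
                        life_years=other.get("life_years", other.get("qaly", 0.0)))
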