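"""Comparative cost-effectiveness analytics.

Turns per-strategy cohort results into incremental cost-effectiveness
ratios, the dominance/efficiency frontier, probabilistic sensitivity
analysis (PSA) with percentile intervals and cost-effectiveness
acceptability curves (by net monetary benefit), number-needed-to-treat /
number-needed-to-harm, and the named one-way sensitivity scenarios.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .microsim import CohortResult

__all__ = ["StrategyOutcome", "FrontierResult", "icer", "efficiency_frontier",
           "run_psa", "nnt_nnh", "sensitivity_suite", "psa_draw"]

#: Willingness-to-pay threshold used for cost-effectiveness verdicts ($/QALY).
DEFAULT_WTP = 50_000.0


@dataclasses.dataclass
class StrategyOutcome:
    """Mean discounted cost and QALYs per person for one strategy."""

    strategy: str
    mean_cost: float
    mean_qaly: float
    replicates: np.ndarray | None = None  # (n_rep, 2) PSA draws of (cost, qaly)

    @classmethod
    def from_result(cls, result: CohortResult) -> "StrategyOutcome":
        return cls(result.strategy, result.mean_cost, result.mean_qaly)


@dataclasses.dataclass
class FrontierResult:
    """Strategies ordered by effectiveness with dominance status and ICERs."""

    table: pd.DataFrame  # strategy, mean_cost, mean_qaly, status, icer, comparator

    @property
    def frontier(self) -> list[str]:
        return self.table.loc[self.table["status"] == "on-frontier",
                              "strategy"].tolist()

    def status(self, strategy: str) -> str:
        return self.table.set_index("strategy").loc[strategy, "status"]


def icer(a: StrategyOutcome, b: StrategyOutcome) -> dict:
    """Incremental cost-effectiveness of ``a`` versus ``b``.

    Returns a verdict dict: ``{"icer": $/QALY}`` when the trade-off is real,
    a dominance verdict when one strategy is both cheaper and more
    effective, or a cost-only comparison when the QALY difference is zero.
    """
    if a.strategy == b.strategy:
        raise ValueError("cannot compare a strategy with itself")
    d_cost = a.mean_cost - b.mean_cost
    d_qaly = a.mean_qaly - b.mean_qaly
    if d_qaly == 0.0:
        return {"verdict": "equal-effect", "delta_cost": d_cost, "icer": None}
    if d_cost <= 0 and d_qaly > 0:
        return {"verdict": f"{a.strategy} dominates {b.strategy}",
                "delta_cost": d_cost, "delta_qaly": d_qaly, "icer": None}
    if d_cost >= 0 and d_qaly < 0:
        return {"verdict": f"{b.strategy} dominates {a.strategy}",
                "delta_cost": d_cost, "delta_qaly": d_qaly, "icer": None}
    return {"verdict": "trade-off", "delta_cost": d_cost, "delta_qaly": d_qaly,
            "icer": d_cost / d_qaly}


def efficiency_frontier(outcomes: list[StrategyOutcome]) -> FrontierResult:
    """Dominance analysis: strict dominance, then extended dominance.

    Strategies are sorted by effectiveness; any strategy that is more
    expensive and no more effective than another is strictly dominated; a
    remaining strategy whose incremental ratio exceeds that of a more
    effective alternative is removed by extended dominance. Frontier ICERs
    (versus the next less effective frontier member) are strictly
    increasing. Exact ties in both cost and effect are kept on the frontier
    and flagged.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two strategies")
    df = pd.DataFrame({
        "strategy": [o.strategy for o in outcomes],
        "mean_cost": [o.mean_cost for o in outcomes],
        "mean_qaly": [o.mean_qaly for o in outcomes],
    }).sort_values(["mean_qaly", "mean_cost"],
                   ascending=[True, False]).reset_index(drop=True)
    status = ["candidate"] * len(df)
    # Strict dominance: more (or equally) effective and strictly cheaper exists.
    for i in range(len(df)):
        ci, qi = df.loc[i, "mean_cost"], df.loc[i, "mean_qaly"]
        for j in range(len(df)):
            if i == j:
                continue
            cj, qj = df.loc[j, "mean_cost"], df.loc[j, "mean_qaly"]
            if (qj >= qi and cj < ci) or (qj > qi and cj <= ci):
                status[i] = "dominated"
                break
    # Extended dominance on the survivors.
    while True:
        idx = [i for i in range(len(df)) if status[i] != "dominated"
               and status[i] != "extended-dominated"]
        removed = False
        for a, b, c in zip(idx, idx[1:], idx[2:]):
            icer_ab = ((df.loc[b, "mean_cost"] - df.loc[a, "mean_cost"])
                       / (df.loc[b, "mean_qaly"] - df.loc[a, "mean_qaly"])
                       if df.loc[b, "mean_qaly"] > df.loc[a, "mean_qaly"] else np.inf)
            icer_bc = ((df.loc[c, "mean_cost"] - df.loc[b, "mean_cost"])
                       / (df.loc[c, "mean_qaly"] - df.loc[b, "mean_qaly"])
                       if df.loc[c, "mean_qaly"] > df.loc[b, "mean_qaly"] else np.inf)
            if icer_ab >= icer_bc and np.isfinite(icer_ab):
                status[b] = "extended-dominated"
                removed = True
                break
        if not removed:
            break
    survivors = [i for i in range(len(df)) if status[i] == "candidate"]
    icers = [np.nan] * len(df)
    comparator = [None] * len(df)
    tie = [False] * len(df)
    for k, i in enumerate(survivors):
        status[i] = "on-frontier"
        if k > 0:
            j = survivors[k - 1]
            dq = df.loc[i, "mean_qaly"] - df.loc[j, "mean_qaly"]
            dc = df.loc[i, "mean_cost"] - df.loc[j, "mean_cost"]
            comparator[i] = df.loc[j, "strategy"]
            if dq == 0 and dc == 0:
                tie[i] = tie[j] = True
            else:
                icers[i] = dc / dq if dq > 0 else np.nan
    df["status"] = status
    df["icer"] = icers
    df["comparator"] = comparator
    df["tie"] = tie
    finite = [v for v in df.loc[df["status"] == "on-frontier", "icer"] if np.isfinite(v)]
    if any(b <= a for a, b in zip(finite, finite[1:])):
        raise AssertionError("frontier ICERs not strictly increasing")
    return FrontierResult(df)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _beta_from_range(point: float, lo: float, hi: float):
    """Beta distribution on [0, 1] moment-matched to mean=point and a normal
    sd implied by treating (lo, hi) as a central 95% interval."""
    sd = max((hi - lo) / (2 * 1.959963984540054), 1e-12)
    m = min(max(point, 1e-9), 1 - 1e-9)
    v = min(sd ** 2, m * (1 - m) * 0.999)
    k = m * (1 - m) / v - 1.0
    return stats.beta(m * k, (1 - m) * k)

def _lognormal_from_range(point: float, lo: float, hi: float):
    """Log-normal with median=point and sigma from the 95% log-range."""
    sigma = max(np.log(hi / lo) / (2 * 1.959963984540054), 1e-12)
    return stats.lognorm(s=sigma, scale=point)


def psa_draw(params, spec: list[dict], rng) -> "object":
    """Draw one joint parameter vector per the PSA specification.

    ``spec`` rows carry ``path`` (dotted parameter path), ``family``
    (``beta`` or ``lognormal``) and the 95% range ``lo``/``hi``. Returns a
    modified copy of ``params``.
    """
    draw = params.copy()
    for row in spec:
        point = params.get(row["path"])
        fam = row["family"]
        if fam == "beta":
            dist = _beta_from_range(point, row["lo"], row["hi"])
        elif fam == "lognormal":
            dist = _lognormal_from_range(point, row["lo"], row["hi"])
        else:
            raise ValueError(f"PSA parameter {row['path']}: unknown family {fam!r}")
        draw.set(row["path"], float(dist.ppf(rng.random())))
    return draw


def run_psa(model_closure, distributions: list[dict], n_replicates: int,
            seed: int, params=None, wtp_grid=None) -> dict:
    """Probabilistic sensitivity analysis.

    ``model_closure(drawn_params, replicate_seed)`` must return
    ``{strategy: (mean_cost, mean_qaly)}`` for one replicate, typically a
    reduced-size cohort run with common random numbers across strategies.
    Returns replicate arrays, percentile 95% intervals per strategy, and the
    cost-effectiveness acceptability curve: per willingness-to-pay point,
    the fraction of replicates in which each strategy has the highest net
    monetary benefit.
    """
    if params is None:
        from .config import default_parameters
        params = default_parameters()
    for row in distributions:
        if "family" not in row or row["family"] not in ("beta", "lognormal"):
            raise ValueError(f"PSA parameter {row.get('path')}: missing or "
                             f"unknown distribution family")
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 150_000.0, 16)
    rng = np.random.default_rng(np.random.Philox(key=(seed << 8) + 17))
    reps = {}
    for r in range(n_replicates):
        drawn = psa_draw(params, distributions, rng)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        out = model_closure(drawn, rep_seed)
        for strat, (cost, qaly) in out.items():
            reps.setdefault(strat, []).append((cost, qaly))
    strategies = sorted(reps)
    arr = {s: np.asarray(reps[s]) for s in strategies}
    counts = {len(v) for v in arr.values()}
    if len(counts) != 1:
        raise ValueError("inconsistent replicate counts across strategies")
    intervals = {
        s: {"cost": tuple(np.percentile(arr[s][:, 0], [2.5, 97.5])),
            "qaly": tuple(np.percentile(arr[s][:, 1], [2.5, 97.5]))}
        for s in strategies}
    acceptability = pd.DataFrame(index=np.asarray(wtp_grid), columns=strategies,
                                 dtype=float)
    costs = np.stack([arr[s][:, 0] for s in strategies])   # (k, n_rep)
    qalys = np.stack([arr[s][:, 1] for s in strategies])
    for w in wtp_grid:
        nmb = w * qalys - costs
        best = np.argmax(nmb, axis=0)
        frac = np.bincount(best, minlength=len(strategies)) / nmb.shape[1]
        acceptability.loc[w] = frac
    return {"replicates": arr, "intervals": intervals,
            "acceptability": acceptability}


def nnt_nnh(strategy: CohortResult, comparator: CohortResult) -> dict:
    """Number needed to treat / to harm versus a comparator arm.

    NNT is the roster size divided by the CHD events averted; NNH divides
    by the excess strategy-related adverse events (statin harms, incident
    diabetes, radiation-attributable cancers). A non-positive denominator is
    reported as a verdict instead of a number.
    """
    if strategy.n_simulated != comparator.n_simulated:
        raise ValueError("rosters differ in size")
    n = strategy.n_simulated
    averted = comparator.counts["chd_events"] - strategy.counts["chd_events"]
    excess = (strategy.strategy_adverse_events
              - comparator.strategy_adverse_events)
    out = {}
    out["nnt"] = n / averted if averted > 0 else None
    if averted <= 0:
        out["nnt_verdict"] = "comparator fewer CHD events"
    out["nnh"] = n / excess if excess > 0 else None
    if excess <= 0:
        out["nnh_verdict"] = "comparator more adverse events"
    return out


def sensitivity_suite(run_fn, scenarios=None) -> dict:
    """Run the named one-way sensitivity scenarios.

    ``run_fn(**overrides)`` must run the full strategy comparison and return
    a :class:`FrontierResult`; scenario names map to the override sets:
    real-world adherence (19-52%) with calcium-score-dependent adherence for
    CAC-aware strategies, statin-disutility multipliers of 10/100/1000,
    aspirin policy variants, CAC radiation dose 0.2-10 mSv, and the
    moderate-dose PCE 5-7.4% guideline variant.
    """
    named = {
        "basecase": {},
        "adherence_19": {"adherence": 0.19,
                         "cac_adherence": CAC_ADHERENCE},
        "adherence_52": {"adherence": 0.52,
                         "cac_adherence": CAC_ADHERENCE},
        "statin_disutility_x10": {"statin_disutility_multiplier": 10.0},
        "statin_disutility_x100": {"statin_disutility_multiplier": 100.0},
        "statin_disutility_x1000": {"statin_disutility_multiplier": 1000.0},
        "aspirin_frs_gated_everywhere": {"aspirin_mode": "frs_gated"},
        "aspirin_cac_positive_only": {"aspirin_mode": "cac_positive"},
        "no_aspirin": {"aspirin_mode": "none"},
        "cac_dose_0.2": {"cac_dose_msv": 0.2},
        "cac_dose_10": {"cac_dose_msv": 10.0},
        "accaha_moderate_5to7.4": {"accaha_moderate_5to7": True},
    }
    if scenarios is None:
        scenarios = list(named)
    results = {}
    for name in scenarios:
        if name not in named:
            raise KeyError(f"unknown scenario {name!r}; choose from {sorted(named)}")
        results[name] = run_fn(**named[name])
    return results


#: Adherence by calcium-score category when a person knows their score.
CAC_ADHERENCE = {"0": 0.36, "1-100": 0.52, "101-400": 0.565,
                 "401-1000": 0.59, ">1000": 0.59}
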