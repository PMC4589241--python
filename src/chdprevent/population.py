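"""Synthetic cohort generation.

Builds seeded rosters of asymptomatic US adults (men 45-75, women 55-75,
diabetics excluded) whose joint distribution of age, Framingham 10-year CHD
risk (FRS), LDL-C, coronary-artery-calcium (CAC) category, C-reactive
protein (CRP) and SHAPE risk-factor count follows configurable tables, so
that every downstream stage of the model is testable without external data.

CRP is modelled log-normal within each (sex, FRS) stratum, fitted to the
published median and 95% interval; LDL-C is normal truncated to a plausible
physiological range; FRS is a category draw plus a uniform within-category
risk so that strategies can branch on categories while the risk engine gets
a continuous number.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FRS_CATEGORIES",
    "FRS_BOUNDS",
    "CAC_CATEGORIES",
    "AGE_BOUNDS",
    "PersonProfile",
    "DistributionTables",
    "fit_crp_lognormal",
    "sample_cohort",
    "count_shape_risk_factors",
]

#: FRS categories used throughout (10-year CHD risk, fractions).
FRS_CATEGORIES = ("0-5", "5-10", "10-15", "15-20", ">20")
FRS_BOUNDS = {
    "0-5": (0.0, 0.05),
    "5-10": (0.05, 0.10),
    "10-15": (0.10, 0.15),
    "15-20": (0.15, 0.20),
    ">20": (0.20, 0.40),
}

#: Agatston-type CAC score categories.
CAC_CATEGORIES = ("0", "1-100", "101-400", "401-1000", ">1000")

#: Cohort entry-age windows per sex.
AGE_BOUNDS = {"male": (45, 75), "female": (55, 75)}

LDL_TRUNCATION = (30.0, 400.0)  # mg/dl

_ROSTER_COLUMNS = [
    "id", "sex", "age_entry", "frs_cat", "frs10", "ldl",
    "cac_category", "crp", "n_shape_risk_factors", "diabetic",
]


@dataclasses.dataclass(frozen=True)
class PersonProfile:
    """One simulated individual's fixed baseline risk attributes."""

    id: int
    sex: str
    age_entry: int
    frs10: float
    ldl: float
    cac_category: str
    crp: float
    n_shape_risk_factors: int = 0
    diabetic: bool = False

    def __post_init__(self) -> None:
        lo, hi = AGE_BOUNDS[self.sex]
        if not lo <= self.age_entry <= hi:
            raise ValueError(
                f"age_entry {self.age_entry} outside [{lo}, {hi}] for sex {self.sex!r}")
        if not 0.0 <= self.frs10 < 1.0:
            raise ValueError(f"frs10 {self.frs10} outside [0, 1)")
        if not LDL_TRUNCATION[0] < self.ldl < LDL_TRUNCATION[1]:
            raise ValueError(f"ldl {self.ldl} outside {LDL_TRUNCATION}")
        if self.crp <= 0:
            raise ValueError("crp must be positive")
        if self.cac_category not in CAC_CATEGORIES:
            raise ValueError(f"unknown CAC category {self.cac_category!r}")
        if self.diabetic:
            raise ValueError("diabetics are excluded from the primary-prevention cohort")

    @property
    def frs_cat(self) -> str:
        return frs_category(self.frs10)


def frs_category(frs10):
    """Map continuous 10-year risk to its category label (vectorised)."""
    edges = [FRS_BOUNDS[c][1] for c in FRS_CATEGORIES[:-1]]
    idx = np.searchsorted(edges, np.asarray(frs10), side="right")
    return np.asarray(FRS_CATEGORIES, dtype=object)[idx]


def fit_crp_lognormal(median: float, upper95: float, lower95: float) -> tuple[float, float]:
    """Fit a log-normal to a CRP summary (median, central 95% interval).

    Returns ``(location, scale)`` of ``ln CRP``; the location equals
    ``ln median`` exactly, and the scale is the least-squares solution on the
    log scale for the 2.5th/97.5th percentiles hitting ``(lower95, upper95)``:
    minimising ``(mu - 1.96 s - ln l)^2 + (mu + 1.96 s - ln u)^2`` in ``s``
    gives ``s = ln(u / l) / (2 * 1.96)``.
    """
    if not (0 < lower95 < median < upper95):
        raise ValueError(
            "CRP summary must satisfy 0 < lower95 < median < upper95; got "
            f"median={median}, lower95={lower95}, upper95={upper95}")
    location = float(np.log(median))
    scale = float(np.log(upper95 / lower95) / (2 * 1.959963984540054))
    return location, scale


def _check_pmf(df: pd.DataFrame, group_cols: list[str], p_col: str, name: str) -> None:
    sums = df.groupby(group_cols, observed=True)[p_col].sum()
    bad = sums[(sums - 1.0).abs() > 1e-9]
    if len(bad):
        raise ValueError(f"{name}: probability rows do not sum to 1: {bad.to_dict()}")
    if ((df[p_col] < 0) | (df[p_col] > 1)).any():
        raise ValueError(f"{name}: probabilities outside [0, 1]")


@dataclasses.dataclass
class DistributionTables:
    """Input distribution tables, loadable from plain CSV files.

    Every probability table is validated on load (rows sum to one within
    1e-9, probabilities in [0, 1]); the roster sampler refuses unvalidated
    tables.
    """

    age_pmf: pd.DataFrame            # sex, age, weight
    frs_pmf: pd.DataFrame            # sex, age_lo, age_hi, frs_cat, probability
    ldl_cond: pd.DataFrame           # sex, frs_cat, mean, sd
    cac_pmf: pd.DataFrame            # sex, age_lo, age_hi, cac_cat, probability
    crp_params: pd.DataFrame         # sex, frs_cat, median, lower95, upper95
    shape_rf_prevalence: pd.DataFrame  # sex, age_lo, age_hi, prevalence
    mortality: pd.DataFrame          # sex, age, annual_prob (non-CHD)
    status_quo_use: pd.DataFrame     # sex, age_lo, age_hi, statin_rate, aspirin_rate
    pce_map: pd.DataFrame            # sex, frs, pce
    radiation_risk: pd.DataFrame     # sex, cancer, risk_per_100k, anchor_age
    validated: bool = False

    _FILES = {
        "age_pmf": "age_distribution.csv",
        "frs_pmf": "frs_distribution.csv",
        "ldl_cond": "ldl_by_frs.csv",
        "cac_pmf": "cac_distribution.csv",
        "crp_params": "crp_by_frs.csv",
        "shape_rf_prevalence": "shape_risk_factors.csv",
        "mortality": "mortality.csv",
        "status_quo_use": "status_quo_use.csv",
        "pce_map": "pce_map.csv",
        "radiation_risk": "radiation_risk.csv",
    }

    @classmethod
    def from_dir(cls, directory: str | Path | None = None) -> "DistributionTables":
        """Load tables from a directory of CSV files (default: packaged)."""
        if directory is None:
            directory = Path(__file__).parent / "data"
        directory = Path(directory)
        kwargs = {}
        for field, fname in cls._FILES.items():
            path = directory / fname
            if not path.exists():
                raise FileNotFoundError(f"missing distribution table {path}")
            try:
                kwargs[field] = pd.read_csv(path)
            except Exception as exc:  # pragma: no cover - delegated to pandas
                raise ValueError(f"{path}: {exc}") from exc
        tables = cls(**kwargs)
        tables.validate()
        return tables

    def validate(self) -> "DistributionTables":
        """Check all probability tables; raises ValueError with the offender."""
        _check_pmf(self.frs_pmf, ["sex", "age_lo"], "probability", "frs_distribution")
        _check_pmf(self.cac_pmf, ["sex", "age_lo"], "probability", "cac_distribution")
        if (self.age_pmf["weight"] < 0).any():
            raise ValueError("age_distribution: negative weight")
        for sex, grp in self.age_pmf.groupby("sex"):
            lo, hi = AGE_BOUNDS[sex]
            if grp["age"].min() < lo or grp["age"].max() > hi:
                raise ValueError(f"age_distribution: ages outside [{lo},{hi}] for {sex}")
        for col in ("prevalence",):
            if ((self.shape_rf_prevalence[col] < 0) | (self.shape_rf_prevalence[col] > 1)).any():
                raise ValueError("shape_risk_factors: prevalence outside [0, 1]")
        if ((self.mortality["annual_prob"] < 0) | (self.mortality["annual_prob"] > 1)).any():
            raise ValueError("mortality: annual_prob outside [0, 1]")
        for col in ("statin_rate", "aspirin_rate"):
            if ((self.status_quo_use[col] < 0) | (self.status_quo_use[col] > 1)).any():
                raise ValueError(f"status_quo_use: {col} outside [0, 1]")
        for sex, grp in self.pce_map.groupby("sex"):
            if not grp.sort_values("frs")["pce"].is_monotonic_increasing:
                raise ValueError(f"pce_map: not monotone nondecreasing for {sex}")
        # CRP summaries must be fit-able; names the offending stratum.
        for _, row in self.crp_params.iterrows():
            try:
                fit_crp_lognormal(row["median"], row["upper95"], row["lower95"])
            except ValueError as exc:
                raise ValueError(
                    f"crp_by_frs ({row['sex']}, FRS {row['frs_cat']}): {exc}") from exc
        if (self.ldl_cond["sd"] <= 0).any():
            raise ValueError("ldl_by_frs: sd must be positive")
        self.validated = True
        return self

    def band_lookup(self, table: pd.DataFrame, sex: str, ages: np.ndarray,
                    value_col: str, key_col: str | None = None,
                    key_vals=None) -> np.ndarray:
        """Look up an age-banded value for an array of ages (optionally keyed)."""
        sub = table[table["sex"] == sex]
        out = np.full(len(ages), np.nan)
        for _, row in sub.iterrows():
            mask = (ages >= row["age_lo"]) & (ages <= row["age_hi"])
            if key_col is not None:
                mask &= np.asarray(key_vals) == row[key_col]
            out[mask] = row[value_col]
        if np.isnan(out).any():
            missing = sorted(set(np.asarray(ages)[np.isnan(out)].tolist()))
            raise KeyError(f"no {value_col} band for sex={sex}, ages {missing[:5]}")
        return out

    def mortality_lookup(self, sex: str, ages: np.ndarray) -> np.ndarray:
        sub = self.mortality[self.mortality["sex"] == sex].sort_values("age")
        amin, amax = sub["age"].iloc[0], sub["age"].iloc[-1]
        clipped = np.clip(ages, amin, amax)
        return sub.set_index("age")["annual_prob"].reindex(clipped).to_numpy()


def sample_cohort(n: int, sex: str, tables: DistributionTables, seed: int) -> pd.DataFrame:
    """Draw a reproducible roster of ``n`` persons of one sex.

    Returns a DataFrame with one row per person and the columns of
    :data:`PersonProfile`. The same ``(n, sex, tables, seed)`` always yields a
    bit-identical roster.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sex not in AGE_BOUNDS:
        raise ValueError(f"unknown sex {sex!r}")
    if not tables.validated:
        raise ValueError("tables must be validated before sampling (call .validate())")
    rng = np.random.default_rng(np.random.Philox(key=seed))

    ages_tab = tables.age_pmf[tables.age_pmf["sex"] == sex]
    probs = ages_tab["weight"].to_numpy(float)
    probs = probs / probs.sum()
    age = rng.choice(ages_tab["age"].to_numpy(), size=n, p=probs)

    # FRS category conditional on age band, then a uniform within-category risk.
    frs_cat = np.empty(n, dtype=object)
    sub = tables.frs_pmf[tables.frs_pmf["sex"] == sex]
    for (lo, hi), grp in sub.groupby(["age_lo", "age_hi"]):
        mask = (age >= lo) & (age <= hi)
        if not mask.any():
            continue
        cats = grp["frs_cat"].to_numpy(object)
        frs_cat[mask] = rng.choice(cats, size=int(mask.sum()),
                                   p=grp["probability"].to_numpy(float))
    if (frs_cat == None).any():  # noqa: E711 - object array sentinel
        raise KeyError(f"frs_distribution: no band covers some ages for {sex}")
    lo_b = np.array([FRS_BOUNDS[c][0] for c in frs_cat])
    hi_b = np.array([FRS_BOUNDS[c][1] for c in frs_cat])
    frs10 = lo_b + rng.random(n) * (hi_b - lo_b)

    # LDL-C: truncated normal conditional on (sex, FRS category).
    ldl = np.empty(n)
    ldl_tab = tables.ldl_cond[tables.ldl_cond["sex"] == sex].set_index("frs_cat")
    for cat in FRS_CATEGORIES:
        mask = frs_cat == cat
        if not mask.any():
            continue
        m, s = ldl_tab.loc[cat, "mean"], ldl_tab.loc[cat, "sd"]
        a, b = (LDL_TRUNCATION[0] - m) / s, (LDL_TRUNCATION[1] - m) / s
        ldl[mask] = stats.truncnorm.ppf(rng.random(int(mask.sum())), a, b, loc=m, scale=s)

    # CAC category conditional on age band.
    cac = np.empty(n, dtype=object)
    sub = tables.cac_pmf[tables.cac_pmf["sex"] == sex]
    for (lo, hi), grp in sub.groupby(["age_lo", "age_hi"]):
        mask = (age >= lo) & (age <= hi)
        if not mask.any():
            continue
        cac[mask] = rng.choice(grp["cac_cat"].to_numpy(object), size=int(mask.sum()),
                               p=grp["probability"].to_numpy(float))

    # CRP: log-normal conditional on (sex, FRS category).
    crp = np.empty(n)
    crp_tab = tables.crp_params[tables.crp_params["sex"] == sex].set_index("frs_cat")
    for cat in FRS_CATEGORIES:
        mask = frs_cat == cat
        if not mask.any():
            continue
        mu, sigma = fit_crp_lognormal(crp_tab.loc[cat, "median"],
                                      crp_tab.loc[cat, "upper95"],
                                      crp_tab.loc[cat, "lower95"])
        crp[mask] = np.exp(mu + sigma * rng.standard_normal(int(mask.sum())))

    roster = pd.DataFrame({
        "id": np.arange(n, dtype=np.int64),
        "sex": sex,
        "age_entry": age.astype(np.int64),
        "frs_cat": frs_cat,
        "frs10": frs10,
        "ldl": ldl,
        "cac_category": cac,
        "crp": crp,
        "diabetic": False,
    })
    roster["n_shape_risk_factors"] = count_shape_risk_factors(roster, tables, seed)
    return roster[_ROSTER_COLUMNS]


def count_shape_risk_factors(roster, tables: DistributionTables, seed: int):
    """Draw the SHAPE risk-factor count (reduced to 0 vs >=1).

    SHAPE's algorithm only branches on having at least one of its risk
    factors (elevated cholesterol or blood pressure, smoking, family
    history, metabolic syndrome); prevalence of >=1 is configured per
    (sex, age band). Any person with FRS >= 10% necessarily carries at
    least one constituent risk factor and always returns >= 1.
    """
    single = isinstance(roster, PersonProfile)
    if single:
        roster = pd.DataFrame([dataclasses.asdict(roster)])
    rng = np.random.default_rng(np.random.Philox(key=(seed << 8) + 7))
    out = np.zeros(len(roster), dtype=np.int64)
    for sex, grp in roster.groupby("sex"):
        prev = tables.band_lookup(tables.shape_rf_prevalence, sex,
                                  grp["age_entry"].to_numpy(), "prevalence")
        out[grp.index.to_numpy()] = (rng.random(len(grp)) < prev).astype(np.int64)
    out[roster["frs10"].to_numpy() >= 0.10] = np.maximum(
        out[roster["frs10"].to_numpy() >= 0.10], 1)
    return int(out[0]) if single else out


def export_roster(roster: pd.DataFrame, path: str | Path) -> None:
    """Write a roster to CSV (one row per person) for inspection/regression."""
    roster.to_csv(path, index=False)
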