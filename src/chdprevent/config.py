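"""Configuration loading, validation and run orchestration.

All model parameters live in versioned plain-text files (YAML scalars, CSV
tables) so that every input is overridable without touching code; a run is
fully determined by (config, seed) and reruns are byte-identical. Every
output file records the seed and a hash of the effective configuration.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .population import DistributionTables, sample_cohort
from .strategies import STRATEGIES, assign
from .microsim import run_cohort, scale_to_population, CohortResult
from .cea import StrategyOutcome, efficiency_frontier, nnt_nnh, FrontierResult

logger = logging.getLogger("chdprevent")

__all__ = ["Parameters", "RunConfig", "default_parameters", "default_tables",
           "load_and_validate", "run_experiment", "make_psa_closure"]

_DATA_DIR = Path(__file__).parent / "data"


class Parameters:
    """Nested parameter mapping with dotted-path access and strict schema.

    The packaged defaults define the schema; loading a file with unknown
    keys, missing keys, or out-of-range values raises a ``ValueError``
    naming the key, the value, and the violated constraint.
    """

    def __init__(self, mapping: dict):
        self._d = mapping

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Parameters":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        return cls(mapping)

    def get(self, path: str):
        node = self._d
        for part in path.split("."):
            try:
                node = node[part]
            except (KeyError, TypeError) as exc:
                raise KeyError(f"unknown parameter path {path!r}") from exc
        return node

    def set(self, path: str, value) -> None:
        parts = path.split(".")
        node = self._d
        for part in parts[:-1]:
            node = node[part]
        if parts[-1] not in node:
            raise KeyError(f"unknown parameter path {path!r}")
        node[parts[-1]] = value

    def copy(self) -> "Parameters":
        return Parameters(copy.deepcopy(self._d))

    def as_dict(self) -> dict:
        return copy.deepcopy(self._d)

    def hash(self) -> str:
        canon = json.dumps(self._d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # -- validation --------------------------------------------------------
    def validate_against(self, reference: "Parameters") -> "Parameters":
        def walk(ref, got, prefix=""):
            if isinstance(ref, dict):
                if not isinstance(got, dict):
                    raise ValueError(f"{prefix or '<root>'}: expected a mapping")
                unknown = set(got) - set(ref)
                if unknown:
                    raise ValueError(
                        f"{prefix or '<root>'}: unknown keys {sorted(unknown)}")
                missing = set(ref) - set(got)
                if missing:
                    raise ValueError(
                        f"{prefix or '<root>'}: missing keys {sorted(missing)}")
                for k in ref:
                    walk(ref[k], got[k], f"{prefix}.{k}".lstrip("."))
            elif isinstance(ref, list):
                if not isinstance(got, list):
                    raise ValueError(f"{prefix}: expected a list")
            else:
                if isinstance(ref, (int, float)) and not isinstance(got, (int, float)):
                    raise ValueError(
                        f"{prefix}: expected a number, got {got!r}")
        walk(reference._d, self._d)
        self._check_ranges()
        return self

    def _check_ranges(self) -> None:
        def walk(node, prefix=""):
            if isinstance(node, dict):
                for k, v in node.items():
                    walk(v, f"{prefix}.{k}".lstrip("."))
                return
            if not isinstance(node, (int, float)) or isinstance(node, bool):
                return
            leaf = prefix.rsplit(".", 1)[-1]
            if "cost" in leaf and node < 0:
                raise ValueError(f"{prefix}: cost must be nonnegative, got {node}")
            if leaf in ("incidence", "annual_incidence", "adherence",
                        "mi_case_fatality", "p_pci", "p_cabg",
                        "p_moderate_severe_ischemia", "ldl_drop_fraction",
                        "low_risk_attenuation") and not 0 <= node <= 1:
                raise ValueError(f"{prefix}: probability/fraction must lie in "
                                 f"[0, 1], got {node}")
            if leaf == "discount_rate" and not 0 <= node < 1:
                raise ValueError(f"{prefix}: discount rate must lie in [0, 1), "
                                 f"got {node}")
            if leaf.startswith("qaly_decrement") and node < 0:
                raise ValueError(f"{prefix}: QALY decrement must be nonnegative")
        walk(self._d)


def default_parameters() -> Parameters:
    params = Parameters.from_yaml(_DATA_DIR / "params.yaml")
    params._check_ranges()
    return params


def default_tables() -> DistributionTables:
    return DistributionTables.from_dir(_DATA_DIR)


@dataclasses.dataclass
class RunConfig:
    """Settings for one orchestrated experiment."""

    n_per_sex: int = 20_000
    horizon: int = 30
    seed: int = 1
    strategies: tuple = tuple(STRATEGIES)
    sexes: tuple = ("male", "female")
    outdir: str | Path = "results"
    params_path: str | Path | None = None
    tables_dir: str | Path | None = None
    # scenario overrides
    adherence: float | None = None
    cac_adherence: dict | None = None
    statin_disutility_multiplier: float = 1.0
    aspirin_mode: str | None = None     # None | frs_gated | cac_positive | none
    cac_dose_msv: float | None = None
    accaha_moderate_5to7: bool = False
    adverse_event_mode: str | None = None
    rounding: str | None = None

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.n_per_sex < 1:
            raise ValueError("n_per_sex must be >= 1")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # where results land does not alter them
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_and_validate(config_path: str | Path | None = None,
                      ) -> tuple[RunConfig, Parameters, DistributionTables]:
    """Load a run config (YAML) plus parameter set and distribution tables.

    With no path, returns packaged defaults. The parameter file is
    cross-checked against the packaged schema; the effective configuration
    is echoed to the log.
    """
    if config_path is None:
        cfg = RunConfig()
    else:
        config_path = Path(config_path)
        if not config_path.exists():
            raise FileNotFoundError(config_path)
        with open(config_path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{config_path}: unknown config keys {sorted(unknown)}")
        if "strategies" in raw:
            raw["strategies"] = tuple(raw["strategies"])
        if "sexes" in raw:
            raw["sexes"] = tuple(raw["sexes"])
        cfg = RunConfig(**raw)
    if cfg.params_path is not None:
        params = Parameters.from_yaml(cfg.params_path).validate_against(
            default_parameters())
    else:
        params = default_parameters()
    tables = (DistributionTables.from_dir(cfg.tables_dir)
              if cfg.tables_dir is not None else default_tables())
    logger.info("effective config: %s (hash %s, params hash %s)",
                dataclasses.asdict(cfg), cfg.hash(), params.hash())
    return cfg, params, tables


def _apply_overrides(cfg: RunConfig, params: Parameters) -> Parameters:
    params = params.copy()
    if cfg.cac_dose_msv is not None:
        params.set("cac.effective_dose_msv", float(cfg.cac_dose_msv))
    if cfg.adverse_event_mode is not None:
        params.set("adverse_event_mode", cfg.adverse_event_mode)
    return params


def apply_aspirin_mode(plan: pd.DataFrame, roster: pd.DataFrame,
                       mode: str | None) -> pd.DataFrame:
    """Aspirin policy variants: gate treat-all on FRS>10%, restrict CAC-based
    strategies to CAC>0, or remove aspirin entirely."""
    if mode is None:
        return plan
    plan = plan.copy()
    if mode == "none":
        plan["aspirin"] = False
    elif mode == "frs_gated":
        plan["aspirin"] &= (roster["frs10"] > 0.10).to_numpy()
    elif mode == "cac_positive":
        if plan["cac_tested"].any():
            plan["aspirin"] &= ((roster["cac_category"] != "0")
                                & plan["cac_tested"]).to_numpy()
    else:
        raise ValueError(f"unknown aspirin mode {mode!r}")
    return plan


def simulate_strategy(strategy: str, roster: pd.DataFrame, params: Parameters,
                      tables: DistributionTables, cfg: RunConfig) -> CohortResult:
    kwargs = {}
    if strategy == "accaha" and cfg.accaha_moderate_5to7:
        kwargs["moderate_5to7"] = True
    plan = assign(strategy, roster, params, tables, seed=cfg.seed, **kwargs)
    plan = apply_aspirin_mode(plan, roster, cfg.aspirin_mode)
    return run_cohort(
        roster, plan, params, tables, horizon=cfg.horizon, seed=cfg.seed,
        adherence=cfg.adherence, cac_adherence=cfg.cac_adherence,
        statin_disutility_multiplier=cfg.statin_disutility_multiplier)


def run_all_strategies(cfg: RunConfig, params: Parameters,
                       tables: DistributionTables) -> dict:
    """Run every requested strategy for every sex on common rosters.

    Returns ``{sex: {strategy: CohortResult}}`` at cohort scale, using
    common random numbers (same seed and draw order) across strategies.
    """
    params = _apply_overrides(cfg, params)
    out = {}
    for si, sex in enumerate(cfg.sexes):
        roster = sample_cohort(cfg.n_per_sex, sex, tables, cfg.seed + 1000 * si)
        out[sex] = {s: simulate_strategy(s, roster, params, tables, cfg)
                    for s in cfg.strategies}
    return out


def frontier_for(results: dict) -> FrontierResult:
    return efficiency_frontier(
        [StrategyOutcome.from_result(r) for r in results.values()])


def make_psa_closure(cfg: RunConfig, tables: DistributionTables, sex: str,
                     n_per_replicate: int = 10_000):
    """Closure for :func:`chdprevent.cea.run_psa`: one reduced-size cohort
    per strategy per replicate, common random numbers within a replicate."""
    def closure(drawn_params, rep_seed):
        sub = dataclasses.replace(cfg, n_per_sex=n_per_replicate,
                                  seed=int(rep_seed) % (2**31 - 1))
        res = run_all_strategies(
            dataclasses.replace(sub, sexes=(sex,)), drawn_params, tables)[sex]
        return {s: (r.mean_cost, r.mean_qaly) for s, r in res.items()}
    return closure


def run_experiment(config: RunConfig | str | Path | None = None,
                   params: Parameters | None = None,
                   tables: DistributionTables | None = None) -> dict:
    """Execute population -> assignment -> simulation -> analysis and write
    the result bundle (CSV tables, JSON summary, log) to the output dir.

    Reruns with identical config and seed are byte-identical; every file
    carries the config hash. On a stage failure the bundle is marked
    incomplete but partial outputs are preserved.
    """
    if not isinstance(config, RunConfig):
        config, params, tables = load_and_validate(config)
    if params is None:
        params = default_parameters()
    if tables is None:
        tables = default_tables()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.hash(),
             "params_hash": params.hash(), "package_version": _version()}
    bundle = {"stamp": stamp, "complete": False}
    try:
        results = run_all_strategies(config, params, tables)
        pop = {"male": params.get("population.male"),
               "female": params.get("population.female")}
        rows = []
        for sex, res in results.items():
            scaled = {s: scale_to_population(r, pop[sex], config.rounding)
                      for s, r in res.items()}
            front = frontier_for(res)
            ref = res.get("status_quo")
            for s, r in res.items():
                row = {"sex": sex, **r.to_series().to_dict(), **stamp}
                sc = scaled[s]
                row.update({f"pop_{k}": v for k, v in sc.counts.items()})
                row["pop_cost"] = sc.cost_discounted
                row["pop_qaly"] = sc.qaly_discounted
                if ref is not None and s != "status_quo":
                    f = pop[sex] / r.n_simulated
                    row["mi_prevented_vs_status_quo"] = f * (
                        (ref.counts["nonfatal_mi"] + ref.counts["fatal_mi"])
                        - (r.counts["nonfatal_mi"] + r.counts["fatal_mi"]))
                    row["qaly_gained_vs_status_quo"] = f * (
                        r.qaly_discounted - ref.qaly_discounted)
                    row["cost_vs_status_quo"] = f * (
                        r.cost_discounted - ref.cost_discounted)
                    nn = nnt_nnh(r, ref)
                    row["nnt_vs_status_quo"] = nn["nnt"]
                    row["nnh_vs_status_quo"] = nn["nnh"]
                rows.append(row)
            front.table.assign(sex=sex, **stamp).to_csv(
                outdir / f"frontier_{sex}.csv", index=False)
            bundle[f"frontier_{sex}"] = front
        tidy = pd.DataFrame(rows)
        tidy.to_csv(outdir / "outcomes.csv", index=False)
        bundle["outcomes"] = tidy
        bundle["results"] = results
        summary = {
            "stamp": stamp,
            "frontier": {sex: bundle[f"frontier_{sex}"].frontier
                         for sex in results},
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        bundle["complete"] = True
    finally:
        with open(outdir / "run.log", "w") as fh:
            fh.write(json.dumps({**stamp, "complete": bundle["complete"]},
                                sort_keys=True) + "\n")
    return bundle


def _version() -> str:
    try:
        from importlib.metadata import version
        return version("chdprevent")
    except Exception:  # pragma: no cover
        return "unknown"
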