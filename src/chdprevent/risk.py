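"""Annual CHD risk engine.

Turns a person's baseline attributes and assigned therapy into an annual
probability of a coronary event. The 10-year Framingham risk is decomposed
into a constant annual hazard; stratification relative risks (CAC or CRP,
for strategies that measured them) are renormalised so that measuring a
marker redistributes risk across the cohort without changing its expected
event count; statin benefit follows the rule of a 0.6% relative CHD risk
reduction per mg/dl of LDL-C lowered, attenuated in low-risk persons; risk
modifiers combine multiplicatively.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RiskParameters",
    "annual_chd_probability",
    "rebase_relative_risk",
    "cohort_mean_rr",
    "statin_relative_risk",
    "aspirin_relative_risk",
    "combined_annual_risk",
]

#: Statin intensities understood by the engine.
STATIN_NONE, STATIN_MODERATE, STATIN_HIGH, STATIN_ROSUVA = (
    "none", "moderate", "high", "rosuvastatin")


@dataclasses.dataclass(frozen=True)
class RiskParameters:
    """Treatment-effect and risk-modifier parameters."""

    chd_rr_per_mg_ldl: float = 0.006
    ldl_drop_moderate: float = 0.34
    ldl_drop_high: float = 0.55
    ldl_drop_rosuva_mg: float = 47.0
    rr_floor: float = 0.10
    low_risk_attenuation: float = 0.19
    low_risk_frs_threshold: float = 0.10
    aspirin_rr_men: float = 0.77
    aspirin_rr_women: float = 1.0
    adherence: float = 0.84

    def __post_init__(self):
        for name in ("ldl_drop_moderate", "ldl_drop_high", "low_risk_attenuation",
                     "adherence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.aspirin_rr_men <= 0 or self.aspirin_rr_women <= 0:
            raise ValueError("aspirin relative risks must be positive")

    @classmethod
    def from_params(cls, params) -> "RiskParameters":
        """Build from a loaded parameter mapping (see :mod:`chdprevent.config`)."""
        g = params.get
        return cls(
            chd_rr_per_mg_ldl=g("statin.chd_rr_per_mg_ldl"),
            ldl_drop_moderate=g("statin.moderate.ldl_drop_fraction"),
            ldl_drop_high=g("statin.high.ldl_drop_fraction"),
            ldl_drop_rosuva_mg=g("statin.rosuvastatin.ldl_drop_mg"),
            rr_floor=g("statin.rr_floor"),
            low_risk_attenuation=g("statin.low_risk_attenuation"),
            low_risk_frs_threshold=g("statin.low_risk_frs_threshold"),
            aspirin_rr_men=g("aspirin.rr_chd_male"),
            aspirin_rr_women=g("aspirin.rr_chd_female"),
            adherence=g("adherence"),
        )


def annual_chd_probability(frs10):
    """Annual CHD event probability from a 10-year risk.

    Constant-hazard (geometric) decomposition: ``p = 1 - (1 - frs10)**(1/10)``,
    so ten independent annual cycles reproduce the 10-year risk exactly.
    """
    frs10 = np.asarray(frs10, dtype=float)
    if np.any(frs10 >= 1.0) or np.any(frs10 < 0.0):
        raise ValueError("frs10 must lie in [0, 1)")
    out = 1.0 - (1.0 - frs10) ** 0.1
    return float(out) if out.ndim == 0 else out


def cohort_mean_rr(p_base, rr, strata=None):
    """Event-weighted mean relative risk, overall or within strata.

    The weighting by baseline probability makes
    ``sum(p_base * rr / mean_rr) == sum(p_base)`` hold exactly, which is the
    conservation property rebasing relies on.
    """
    p_base = np.asarray(p_base, float)
    rr = np.asarray(rr, float)
    if strata is None:
        return float(np.sum(p_base * rr) / np.sum(p_base))
    strata = np.asarray(strata)
    out = np.empty_like(p_base)
    for s in np.unique(strata):
        mask = strata == s
        denom = p_base[mask].sum()
        out[mask] = (p_base[mask] * rr[mask]).sum() / denom if denom > 0 else 1.0
    return out


def rebase_relative_risk(p_base, rr, population_mean_rr):
    """Apply a stratification relative risk, renormalised to the cohort mean.

    ``p_base * rr / population_mean_rr`` redistributes risk so that the
    cohort's expected event count implied by FRS alone is preserved.
    Results above 1 are clipped with a logged warning.
    """
    p = np.asarray(p_base, float) * np.asarray(rr, float) / np.asarray(
        population_mean_rr, float)
    n_over = int(np.sum(p > 1.0))
    if n_over:
        logger.warning("rebase_relative_risk: clipping %d probabilities > 1", n_over)
        p = np.minimum(p, 1.0)
    return float(p) if p.ndim == 0 else p


def statin_relative_risk(ldl_baseline, intensity, params: RiskParameters,
                         low_risk=False):
    """Relative risk of CHD on statin therapy, in (0, 1].

    The LDL-C drop is a fixed fraction of baseline (34% moderate, 55% high
    intensity) or a flat 47 mg/dl for rosuvastatin 20 mg; each mg/dl lowered
    removes ``chd_rr_per_mg_ldl`` (0.6%) of the person's CHD risk, floored at
    ``rr_floor``. In low-risk persons the risk *reduction* is attenuated by
    ``low_risk_attenuation``. Vectorised over persons.
    """
    ldl = np.asarray(ldl_baseline, dtype=float)
    if np.any(ldl <= 0):
        raise ValueError("ldl_baseline must be positive")
    intensity = np.asarray(intensity, dtype=object)
    scalar = intensity.ndim == 0
    intensity = np.atleast_1d(intensity)
    ldl = np.broadcast_to(np.atleast_1d(ldl), intensity.shape).astype(float)
    low_risk = np.broadcast_to(np.atleast_1d(np.asarray(low_risk, bool)),
                               intensity.shape)

    drop = np.zeros_like(ldl)
    drop[intensity == STATIN_MODERATE] = (
        params.ldl_drop_moderate * ldl[intensity == STATIN_MODERATE])
    drop[intensity == STATIN_HIGH] = (
        params.ldl_drop_high * ldl[intensity == STATIN_HIGH])
    drop[intensity == STATIN_ROSUVA] = params.ldl_drop_rosuva_mg
    rr = np.maximum(1.0 - params.chd_rr_per_mg_ldl * drop, params.rr_floor)
    rr = np.where(intensity == STATIN_NONE, 1.0, rr)
    reduction = (1.0 - rr) * np.where(low_risk, 1.0 - params.low_risk_attenuation, 1.0)
    rr = 1.0 - reduction
    return float(rr[0]) if scalar else rr


def aspirin_relative_risk(sex, treated=True, params: RiskParameters | None = None):
    """Relative risk of CHD on low-dose aspirin: 0.77 for treated men, else 1."""
    params = params or RiskParameters()
    sex = np.asarray(sex, dtype=object)
    scalar = sex.ndim == 0
    sex = np.atleast_1d(sex)
    treated = np.broadcast_to(np.atleast_1d(np.asarray(treated, bool)), sex.shape)
    rr = np.where(treated & (sex == "male"), params.aspirin_rr_men,
                  np.where(treated & (sex == "female"), params.aspirin_rr_women, 1.0))
    return float(rr[0]) if scalar else rr


def combined_annual_risk(frs10, strat_rr_rebased=1.0, statin_rr=1.0,
                         aspirin_rr=1.0, adherent=True):
    """Annual CHD probability with all modifiers combined multiplicatively.

    ``strat_rr_rebased`` is the already-rebased CAC/CRP factor (1 when the
    strategy did not measure the marker). Non-adherent persons revert to
    relative risk 1 for both medications.
    """
    p = annual_chd_probability(frs10)
    adherent = np.asarray(adherent, bool)
    statin_rr = np.where(adherent, statin_rr, 1.0)
    aspirin_rr = np.where(adherent, aspirin_rr, 1.0)
    out = np.clip(p * strat_rr_rebased * statin_rr * aspirin_rr, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out
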