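"""Synthetic assessment panels and validation elements with known truth.

No public deposit of real resident-assessment data exists, so everything in
this package is exercised on simulated panels whose ground truth is known.
The generator emulates the statistical structure that risk adjustment
exists to untangle:

* each facility f carries a latent quality effect u_f (logit scale; higher
  = more adverse outcomes, i.e. worse care);
* residents carry a latent frailty that drives case-mix covariates and the
  stratifier, and whose facility-level mean is *confounded* with u_f at a
  configurable correlation — the situation in which raw rates misattribute
  case mix to quality;
* cross-sectional outcomes are Bernoulli with logit = alpha + beta.x + u_f,
  with alpha calibrated so the realized marginal rate matches the
  configured base rate;
* change-type outcomes (pain level, ADL self-performance) evolve as
  quarterly Markov transitions whose deterioration rate loads on u_f;
* restraint use is a near-immutable resident trait (high quarter-to-quarter
  stability);
* item missingness and per-quarter new-admission flags mimic field data.

A facility-level validation-element table (61 preventive + 92 responsive
columns) loads on u_f with opposite signs — prevention correlates with good
care, responsive activity with high problem rates — plus independent noise.

Identical seeds reproduce identical output bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .evaluation import ValidationElements

__all__ = ["SimulationConfig", "simulate_panel", "simulate_validation_elements"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults follow the study design being emulated where one is stated
    (209 facilities, 3 calendar quarters, ~8% item missingness, 61/92
    validation elements) and otherwise sit at values typical for chronic
    nursing-home care (base outcome rate 0.25; ~30 sampled residents per
    facility).
    """

    n_facilities: int = 209
    residents_per_facility: int = 30
    n_quarters: int = 3
    #: SD of the facility quality effect u_f on the logit scale
    quality_sd: float = 0.5
    #: correlation between a facility's case-mix shift and u_f
    confounding: float = 0.5
    #: logit-scale slopes of (cognition_scale, comorbidity_index)
    covariate_effects: tuple = (0.8, 0.5)
    #: target marginal rate of the cross-sectional outcome (pressure ulcer)
    base_rate: float = 0.25
    #: loading of the stratifier (adl_long_form) on resident frailty
    stratifier_loading: float = 0.8
    #: SD of the facility case-mix shift applied to resident frailty
    #: (within-facility frailty SD is 1, so 1.0 puts half the frailty
    #: variance between facilities).  The emulated reference world pools
    #: care sectors — long-stay custodial, post-acute rehabilitation,
    #: complex continuing care — whose resident mixes differ grossly, so
    #: between-facility case-mix separation rivals or exceeds the quality
    #: signal; that is the regime third-generation adjustment exists for.
    case_mix_shift_sd: float = 1.0
    new_admission_rate: float = 0.10
    item_missingness: float = 0.08
    pain_init_rate: float = 0.30
    pain_worsen_rate: float = 0.15
    pain_improve_rate: float = 0.25
    adl_decline_rate: float = 0.15
    adl_improve_rate: float = 0.20
    restraint_rate: float = 0.12
    #: per-quarter probability that restraint status flips (measurement /
    #: practice noise on an otherwise immutable trait)
    restraint_flip_rate: float = 0.02
    #: |loading| of validation elements on the standardized quality effect
    element_loading: float = 0.5
    element_missingness: float = 0.08
    n_preventive: int = 61
    n_responsive: int = 92
    seed: int = 0

    def validate(self) -> None:
        rates = {
            "base_rate": self.base_rate,
            "new_admission_rate": self.new_admission_rate,
            "item_missingness": self.item_missingness,
            "pain_init_rate": self.pain_init_rate,
            "pain_worsen_rate": self.pain_worsen_rate,
            "pain_improve_rate": self.pain_improve_rate,
            "adl_decline_rate": self.adl_decline_rate,
            "adl_improve_rate": self.adl_improve_rate,
            "restraint_rate": self.restraint_rate,
            "restraint_flip_rate": self.restraint_flip_rate,
            "element_missingness": self.element_missingness,
        }
        for name, r in rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name}={r} outside [0, 1]")
        if not (0.0 < self.base_rate < 1.0):
            raise ValueError("base_rate must lie strictly in (0, 1)")
        if not (-1.0 <= self.confounding <= 1.0):
            raise ValueError(f"confounding={self.confounding} outside [-1, 1]")
        if self.quality_sd < 0:
            raise ValueError("quality_sd must be non-negative")
        for name in ("n_facilities", "residents_per_facility", "n_quarters",
                     "n_preventive", "n_responsive"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "covariate_effects" in d:
            d["covariate_effects"] = tuple(d["covariate_effects"])
        return cls(**d)


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept alpha with mean(expit(alpha + eta)) equal to ``target``."""
    f = lambda a: expit(a + eta).mean() - target
    return brentq(f, -30.0, 30.0, xtol=1e-10)


def _transition(levels, worsen_p, improve_p, rng, lo, hi):
    """One quarterly Markov step: up one level w.p. worsen, down w.p. improve."""
    improve_p = np.minimum(improve_p, 1.0 - worsen_p)
    u = rng.uniform(size=levels.shape)
    out = levels.copy()
    out[u < worsen_p] += 1
    out[(u >= worsen_p) & (u < worsen_p + improve_p)] -= 1
    return np.clip(out, lo, hi)


def simulate_panel(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an assessment panel and its facility truth table.

    Returns ``(panel, truth)``: the panel has one row per resident-quarter
    with the items the shipped QI library references; the truth table maps
    each facility to its quality effect ``u_f`` and case-mix shift.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    F, R, Q = config.n_facilities, config.residents_per_facility, config.n_quarters
    N = F * R

    # facility quality and confounded case-mix shift
    z_u = rng.standard_normal(F)
    z_e = rng.standard_normal(F)
    u_f = config.quality_sd * z_u
    rho = config.confounding
    shift_f = config.case_mix_shift_sd * (rho * z_u + np.sqrt(1.0 - rho**2) * z_e)

    fac_idx = np.repeat(np.arange(F), R)
    frailty_within = rng.standard_normal(N)
    frailty = shift_f[fac_idx] + frailty_within
    lam = 0.7
    cognition = lam * frailty + np.sqrt(1 - lam**2) * rng.standard_normal(N)
    comorbidity = lam * frailty + np.sqrt(1 - lam**2) * rng.standard_normal(N)
    # the stratifier tracks within-facility risk heterogeneity; facility-level
    # case-mix confounding enters through the covariate means, not here
    s_lam = config.stratifier_loading
    stratifier = s_lam * frailty_within + np.sqrt(max(1 - s_lam**2, 0.0)) * rng.standard_normal(N)

    b1, b2 = config.covariate_effects
    eta = b1 * cognition + b2 * comorbidity + u_f[fac_idx]
    alpha = _calibrate_intercept(eta, config.base_rate)
    p_ulcer = expit(alpha + eta)

    # initial states
    p_pain = expit(logit(config.pain_init_rate) + 0.5 * frailty)
    pain = (rng.uniform(size=N) < p_pain).astype(int)
    pain += (pain == 1) & (rng.uniform(size=N) < 0.3)  # severe among painful
    adl = np.clip(np.round(1.5 + 0.8 * frailty + rng.standard_normal(N)), 0, 4).astype(int)
    restraint = (
        rng.uniform(size=N)
        < expit(logit(config.restraint_rate) + 0.4 * frailty + u_f[fac_idx])
    ).astype(int)

    pain_worsen = expit(logit(config.pain_worsen_rate) + 0.3 * frailty + u_f[fac_idx])
    pain_improve = expit(logit(config.pain_improve_rate) - u_f[fac_idx])
    adl_decline = expit(logit(config.adl_decline_rate) + 0.3 * frailty + u_f[fac_idx])
    adl_improve = expit(logit(config.adl_improve_rate) - u_f[fac_idx])

    facility_ids = np.array([f"F{f:04d}" for f in range(F)])
    resident_ids = np.array([f"R{f:04d}_{r:04d}" for f in range(F) for r in range(R)])

    frames = []
    for q in range(1, Q + 1):
        if q > 1:
            pain = _transition(pain, pain_worsen, pain_improve, rng, 0, 2)
            adl = _transition(adl, adl_decline, adl_improve, rng, 0, 4)
            flip = rng.uniform(size=N) < config.restraint_flip_rate
            restraint = np.where(flip, 1 - restraint, restraint)
        ulcer = (rng.uniform(size=N) < p_ulcer).astype(int)
        new_adm = rng.uniform(size=N) < config.new_admission_rate
        frames.append(pd.DataFrame({
            "resident_id": resident_ids,
            "facility_id": facility_ids[fac_idx],
            "quarter": q,
            "new_admission": new_adm,
            "cognition_scale": cognition,
            "comorbidity_index": comorbidity,
            "adl_long_form": stratifier,
            "pressure_ulcer": ulcer,
            "pain_level": pain.copy(),
            "adl_self": adl.copy(),
            "physical_restraint": restraint.copy(),
        }))
    panel = pd.concat(frames, ignore_index=True)

    # item missingness on covariates and the stratifier
    if config.item_missingness > 0:
        for col in ("cognition_scale", "comorbidity_index", "adl_long_form"):
            mask = rng.uniform(size=len(panel)) < config.item_missingness
            panel.loc[mask, col] = np.nan

    truth = pd.DataFrame({
        "facility_id": facility_ids,
        "u_f": u_f,
        "case_mix_shift": shift_f,
    })
    return panel, truth


def simulate_validation_elements(
    config: SimulationConfig, truth: pd.DataFrame
) -> ValidationElements:
    """Facility-level care-process element table correlated with true quality.

    Preventive columns load *negatively* on the (standardized) adverse-quality
    effect — facilities that prevent well have fewer problems — while
    responsive columns load *positively*: responsive activity tracks the
    problem rates it reacts to.  Independent unit-variance noise and random
    missingness are added on top.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 941])
    u = truth["u_f"].to_numpy(dtype=float)
    u_std = u / config.quality_sd if config.quality_sd > 0 else np.zeros_like(u)
    F = u.size
    load = config.element_loading

    prev = -load * u_std[:, None] + rng.standard_normal((F, config.n_preventive))
    resp = load * u_std[:, None] + rng.standard_normal((F, config.n_responsive))
    values = np.column_stack([prev, resp])
    if config.element_missingness > 0:
        mask = rng.uniform(size=values.shape) < config.element_missingness
        values = np.where(mask, np.nan, values)

    cols = [f"prev_{j + 1:03d}" for j in range(config.n_preventive)] + [
        f"resp_{j + 1:03d}" for j in range(config.n_responsive)
    ]
    classes = ["preventive"] * config.n_preventive + ["responsive"] * config.n_responsive
    frame = pd.DataFrame(values, index=truth["facility_id"].to_numpy(), columns=cols)
    frame.index.name = "facility_id"
    return ValidationElements(frame, pd.Series(classes, index=cols))
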